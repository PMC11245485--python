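"""Synthetic multi-omic data with planted ground truth.

Generates every input the hub-regulator pipeline consumes at desk scale,
mirroring the statistical structure the analysis assumes:

* stress-induced differential expression driven by planted hub regulators,
  each hub steering a disjoint target module through a per-sample latent
  activity — the DEG submatrix is low-rank-plus-noise, and because each
  module's gene-loading pattern is sparse (nonzero only on its members)
  the gene-space sources are super-Gaussian, the structure ICA expects;
* a three-group genotype panel (wild *O. rufipogon* plus the cultivated
  *japonica* / *indica* groups) under the Balding–Nichols drift model,
  with a low-diversity sweep region planted in the cultivated groups, a
  causal promoter InDel affecting the phenotype, and an allele-frequency
  cline along mean precipitation;
* quantitative phenotypes (an i-trait in the GPAR-R style) with a causal
  dosage effect, a kinship-structured polygenic term and white noise.

All randomness flows from ``SimConfig.seed`` through named child streams
(one per generator), so each generator is independently reproducible and
identical configs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, tpm_normalize
from .genotypes import GenotypePanel

__all__ = ["SimConfig", "SimTruth", "simulate_expression", "simulate_genotypes",
           "simulate_geography", "simulate_phenotypes", "simulate_bundle",
           "write_bundle"]

# gene-slot layout on the simulated chromosome (bp)
PROMOTER_BP = 3000
BODY_BP = 3000
GAP_BP = 1000
SLOT_BP = PROMOTER_BP + BODY_BP + GAP_BP

# named child streams of the master seed
_STREAMS = {"expression": 0, "genotypes": 1, "geography": 2, "phenotypes": 3}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Counts are desk-scale stand-ins for the real study's panels
    (hundreds of cultivars, thousands of variants); effect sizes and
    noise levels are set so planted structure is recoverable but not
    trivially so.
    """

    seed: int
    n_genes: int = 2000
    n_regulators: int = 20
    n_planted_hubs: int = 3
    n_targets_per_hub: int = 30
    n_samples_per_condition: int = 12
    conditions: tuple = ("control", "drought", "heat")
    de_log2fc: float = 3.0
    expr_noise_sd: float = 0.3
    nb_dispersion: float = 0.05
    hub_activity_scale: float = 0.7   # sd of per-sample hub latent activity
    library_size: int = 2_000_000
    n_extra_de: int = 300             # stress-responsive genes outside the modules
    n_accessions: int = 70            # per population group
    n_variants: int = 1000
    fst: float = 0.3
    causal_beta: float = 0.8
    h2_polygenic: float = 0.4
    sweep_window: tuple | None = None  # (start, end) bp; default: hub 1 gene region
    precip_gradient: float = 0.6
    chrom: str = "chr6"

    def __post_init__(self):
        for name in ("n_genes", "n_regulators", "n_planted_hubs",
                     "n_targets_per_hub", "n_samples_per_condition",
                     "n_accessions", "n_variants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if not (0.0 <= self.h2_polygenic <= 1.0):
            raise ValueError("h2_polygenic must lie in [0, 1]")
        if not (-1.0 <= self.precip_gradient <= 1.0):
            raise ValueError("precip_gradient must lie in [-1, 1]")
        if self.n_planted_hubs > self.n_regulators:
            raise ValueError("n_planted_hubs cannot exceed n_regulators")
        n_net = (self.n_regulators + self.n_planted_hubs * self.n_targets_per_hub
                 + self.n_extra_de)
        if n_net > self.n_genes:
            raise ValueError(
                f"regulators + planted DE genes ({n_net}) exceed n_genes ({self.n_genes})")
        span = self.genome_span()
        if self.sweep_window is not None:
            s, e = self.sweep_window
            if not (1 <= s < e <= span):
                raise ValueError(f"sweep_window {self.sweep_window} outside 1..{span}")

    def genome_span(self) -> int:
        return self.n_regulators * SLOT_BP

    def gene_regions(self) -> dict:
        """Regulator id -> (chrom, body_start, body_end), 1-based inclusive."""
        out = {}
        for i in range(self.n_regulators):
            slot = i * SLOT_BP
            out[f"NAC{i + 1:03d}"] = (self.chrom, slot + PROMOTER_BP + 1,
                                      slot + PROMOTER_BP + BODY_BP)
        return out

    def effective_sweep_window(self) -> tuple:
        """Planted sweep interval; defaults to hub 1's promoter + gene body."""
        if self.sweep_window is not None:
            return tuple(self.sweep_window)
        return (1, PROMOTER_BP + BODY_BP)


@dataclass
class SimTruth:
    """Planted ground truth for one synthetic bundle."""

    hub_gene_ids: list = field(default_factory=list)
    target_map: dict = field(default_factory=dict)
    de_gene_ids: dict = field(default_factory=dict)
    causal_variant_id: str | None = None
    sweep_window: tuple | None = None
    cline_variant_id: str | None = None
    gene_regions: dict = field(default_factory=dict)

    def merge(self, other: "SimTruth") -> "SimTruth":
        merged = SimTruth(**dataclasses.asdict(self))
        for f in dataclasses.fields(other):
            v = getattr(other, f.name)
            if v not in (None, [], {}):
                setattr(merged, f.name, v)
        return merged

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["target_map"] = {k: sorted(v) for k, v in self.target_map.items()}
        d["de_gene_ids"] = {k: sorted(v) for k, v in self.de_gene_ids.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["sweep_window"] = tuple(d["sweep_window"]) if d.get("sweep_window") else None
        d["gene_regions"] = {k: tuple(v) for k, v in d.get("gene_regions", {}).items()}
        return cls(**d)


def _all_profiles(n_stress: int) -> list:
    """Every nonzero condition-response sign profile over the stresses,
    ordered: induced-everywhere first, then condition-specific, then
    mixed/repressed."""
    import itertools
    pats = [p for p in itertools.product((1, 0, -1), repeat=max(n_stress, 1))
            if any(p)]
    pats.sort(key=lambda p: (sum(v < 0 for v in p), sum(v == 0 for v in p), p))
    return pats


def _hub_profiles(n_hubs: int, n_stress: int) -> list:
    """Distinct profiles, one per planted hub; cycles if hubs outnumber
    the distinct patterns."""
    pats = _all_profiles(n_stress)
    return [pats[i % len(pats)] for i in range(n_hubs)]


def _gene_ids(config: SimConfig) -> list:
    regs = [f"NAC{i + 1:03d}" for i in range(config.n_regulators)]
    rest = [f"OsG{i + 1:05d}" for i in range(config.n_genes - config.n_regulators)]
    return regs + rest


def regulator_ids(config: SimConfig) -> list:
    return _gene_ids(config)[: config.n_regulators]


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Counts + TPM with planted hub-driven stress response.

    Each planted hub h carries a condition-response profile r_h (a vector
    over the stress conditions with entries in {+1, 0, -1}; hubs get
    distinct profiles — shared, drought-specific, heat-specific, ... — so
    their modules are separable co-expression programs). Its latent
    activity per sample is
    ``a_hs = de_log2fc * r_h[condition(s)] + N(0, hub_activity_scale^2)``;
    the hub's own log2 expression is baseline + a_hs, and each of its
    targets follows ``baseline + slope * a_hs + N(0, expr_noise_sd)`` with
    slope drawn from +-U(0.7, 1.3). Genes outside the planted modules have
    condition-independent means. Counts are negative-binomial around the
    implied per-sample abundances. The per-condition DEG truth contains a
    module exactly when its hub's profile is nonzero for that condition.
    """
    rng = _rng(config, "expression")
    genes = _gene_ids(config)
    n_g = config.n_genes
    hubs = genes[: config.n_planted_hubs]

    non_reg = genes[config.n_regulators:]
    n_targets = config.n_planted_hubs * config.n_targets_per_hub
    picked = rng.choice(len(non_reg), size=n_targets + config.n_extra_de,
                        replace=False)
    target_pool, extra_pool = picked[:n_targets], picked[n_targets:]
    target_map = {}
    for h_i, hub in enumerate(hubs):
        sel = target_pool[h_i * config.n_targets_per_hub:(h_i + 1) * config.n_targets_per_hub]
        target_map[hub] = [non_reg[j] for j in sel]
    extra_genes = [non_reg[j] for j in extra_pool]

    conditions = list(config.conditions)
    n_per = config.n_samples_per_condition
    sample_ids, meta_rows = [], []
    varieties = ("ZH11", "DJ")
    stages = ("seedling", "reproductive")
    for cond in conditions:
        for r in range(n_per):
            sid = f"{cond}_{r + 1}"
            sample_ids.append(sid)
            meta_rows.append({"variety": varieties[r % 2], "condition": cond,
                              "stage": stages[(r // 2) % 2], "replicate": r + 1})
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    n_s = len(sample_ids)
    stress_conditions = [c for c in conditions if c != "control"]
    profiles = _hub_profiles(len(hubs), len(stress_conditions))
    cond_idx = {c: i for i, c in enumerate(stress_conditions)}
    response = np.zeros((len(hubs), n_s))
    for j, cond in enumerate(meta["condition"]):
        if cond in cond_idx:
            for h_i in range(len(hubs)):
                response[h_i, j] = profiles[h_i][cond_idx[cond]]

    baseline = rng.uniform(3.0, 9.0, size=n_g)
    # planted genes start from a modest baseline so their stress induction
    # stays a small fraction of the library and TPM normalisation does not
    # shift the apparent expression of unrelated genes
    gene_index = {g: i for i, g in enumerate(genes)}
    planted_idx = [gene_index[g] for g in hubs] + \
        [gene_index[t] for h in hubs
         for t in target_map[h]] + [gene_index[g] for g in extra_genes]
    baseline[planted_idx] = rng.uniform(3.0, 6.0, size=len(planted_idx))
    log2expr = np.tile(baseline[:, None], (1, n_s))
    for h_i, hub in enumerate(hubs):
        act = config.de_log2fc * response[h_i] \
            + rng.normal(0.0, config.hub_activity_scale, size=n_s)
        log2expr[gene_index[hub]] = baseline[gene_index[hub]] + act
        for tgt in target_map[hub]:
            slope = rng.uniform(0.7, 1.3) * rng.choice([-1.0, 1.0])
            g = gene_index[tgt]
            log2expr[g] = baseline[g] + slope * act \
                + rng.normal(0.0, config.expr_noise_sd, size=n_s)

    # singleton stress-responsive genes outside the hub modules: each runs
    # its own condition profile with independent activity noise (the bulk
    # of a real stress DEG set is not regulator-module structured)
    all_pats = _all_profiles(len(stress_conditions))
    extra_profile = {}
    for gid in extra_genes:
        pat = all_pats[rng.integers(0, len(all_pats))]
        extra_profile[gid] = pat
        resp = np.array([pat[cond_idx[c]] if c in cond_idx else 0.0
                         for c in meta["condition"]])
        slope = rng.uniform(0.7, 1.3) * rng.choice([-1.0, 1.0])
        g = gene_index[gid]
        log2expr[g] = baseline[g] + slope * config.de_log2fc * resp \
            + rng.normal(0.0, config.expr_noise_sd, size=n_s)

    # baseline biological noise for non-planted genes
    planted = set(hubs) | {t for ts in target_map.values() for t in ts} \
        | set(extra_genes)
    for g, gid in enumerate(genes):
        if gid not in planted:
            log2expr[g] += rng.normal(0.0, config.expr_noise_sd, size=n_s)

    gene_lengths = rng.integers(500, 5001, size=n_g).astype(float)
    abundance = 2.0 ** log2expr
    frac = (abundance * gene_lengths[:, None])
    frac /= frac.sum(axis=0, keepdims=True)
    mu = config.library_size * frac
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    expr = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        counts=counts,
        tpm=tpm_normalize(counts, gene_lengths),
        gene_lengths=gene_lengths,
        metadata=meta,
    )
    de_gene_ids = {}
    for cond in stress_conditions:
        members = []
        for h_i, hub in enumerate(hubs):
            if profiles[h_i][cond_idx[cond]] != 0:
                members.append(hub)
                members.extend(target_map[hub])
        members.extend(g for g in extra_genes
                       if extra_profile[g][cond_idx[cond]] != 0)
        de_gene_ids[cond] = sorted(members)
    truth = SimTruth(
        hub_gene_ids=list(hubs),
        target_map={h: list(ts) for h, ts in target_map.items()},
        de_gene_ids=de_gene_ids,
        gene_regions=config.gene_regions(),
    )
    return expr, truth


def simulate_geography(config: SimConfig) -> pd.DataFrame:
    """Accession geography: longitude, latitude, mean precipitation, group.

    Precipitation is lognormal-ish around ~1200 mm; coordinates are drawn
    in a South/East-Asian bounding box and carry no planted signal (the
    cline is planted on precipitation, the covariate the pipeline tests).
    """
    rng = _rng(config, "geography")
    rows = []
    for group, prefix in (("O. ruf", "WR"), ("japonica", "JAP"), ("indica", "IND")):
        for i in range(config.n_accessions):
            rows.append({
                "accession": f"{prefix}{i + 1:03d}",
                "longitude": rng.uniform(70.0, 125.0),
                "latitude": rng.uniform(8.0, 35.0),
                "precip_mm": max(50.0, rng.normal(1200.0, 350.0)),
                "group": group,
            })
    return pd.DataFrame(rows).set_index("accession")


def _balding_nichols_freqs(rng, p_anc, fst, n_pops):
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(a[None, :].repeat(n_pops, 0), b[None, :].repeat(n_pops, 0))


def simulate_genotypes(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Three-group Balding–Nichols panel with planted sweep, causal InDel, cline.

    Subpopulation allele frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F)
    around a uniform ancestral frequency. Inside the sweep window the two
    cultivated groups are pushed to a shared near-fixed frequency, which
    depresses their nucleotide diversity relative to the wild group. The
    causal promoter InDel is excluded from the push (it must segregate in
    the cultivated panel to carry the association) and is drawn with a
    per-accession success probability linear in standardised precipitation,
    which plants the precipitation cline; it doubles as the cline variant.
    """
    rng = _rng(config, "genotypes")
    geo = simulate_geography(config)
    accessions = list(geo.index)
    group_arr = geo["group"].to_numpy(dtype=object)
    n_acc = len(accessions)
    span = config.genome_span()

    pos = np.sort(rng.choice(np.arange(1, span + 1), size=config.n_variants,
                             replace=False))
    # causal promoter InDel in the middle of hub 1's promoter
    causal_pos = PROMOTER_BP // 2
    insert_at = np.searchsorted(pos, causal_pos)
    if insert_at < len(pos) and pos[insert_at] == causal_pos:
        pos = np.delete(pos, insert_at)
        insert_at = np.searchsorted(pos, causal_pos)
    pos = np.insert(pos, insert_at, causal_pos)
    n_var = len(pos)
    causal_idx = int(insert_at)

    chrom_num = "".join(ch for ch in config.chrom if ch.isdigit()) or "1"
    vids = [f"vg{int(chrom_num):02d}{p:07d}" for p in pos]
    bases = np.array(list("ACGT"))
    ref = list(bases[rng.integers(0, 4, size=n_var)])
    alt = [bases[(bases != r)][rng.integers(0, 3)] for r in ref]
    ref[causal_idx], alt[causal_idx] = "G", "GTATA"   # promoter insertion

    p_anc = rng.uniform(0.05, 0.95, size=n_var)
    pop_freq = _balding_nichols_freqs(rng, p_anc, config.fst, 3)  # wild, jap, ind

    sweep = config.effective_sweep_window()
    in_sweep = (pos >= sweep[0]) & (pos <= sweep[1])
    in_sweep[causal_idx] = False
    fixed_to = np.where(p_anc >= 0.5, 0.99, 0.01)
    for cult in (1, 2):
        pop_freq[cult, in_sweep] = fixed_to[in_sweep]

    group_of = {"O. ruf": 0, "japonica": 1, "indica": 2}
    pop_idx = np.array([group_of[g] for g in group_arr])
    freq_mat = pop_freq[pop_idx, :].T                  # variants x accessions
    dosage = rng.binomial(2, freq_mat).astype(np.int8)

    # causal/cline variant: dosage probability linear in standardised precip
    precip = geo["precip_mm"].to_numpy(dtype=float)
    z = (precip - precip.mean()) / precip.std(ddof=0)
    r = float(np.clip(config.precip_gradient, -0.99, 0.99))
    a = np.sign(r) * np.sqrt(0.5 * r * r / (4.0 - 2.0 * r * r))
    p_i = np.clip(0.5 + a * z, 0.02, 0.98)
    dosage[causal_idx] = rng.binomial(2, p_i).astype(np.int8)

    panel = GenotypePanel(
        variant_ids=vids,
        chrom=np.array([config.chrom] * n_var, dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        dosage=dosage,
        accession_ids=accessions,
        groups=group_arr,
    )
    truth = SimTruth(
        causal_variant_id=vids[causal_idx],
        cline_variant_id=vids[causal_idx],
        sweep_window=sweep,
        gene_regions=config.gene_regions(),
    )
    return panel, truth


def simulate_phenotypes(panel: GenotypePanel, truth: SimTruth,
                        config: SimConfig) -> pd.DataFrame:
    """GPAR-R-style i-trait for the cultivated accessions.

    y = causal_beta * dosage + u + e with u ~ N(0, h2 * K) on the
    cultivated kinship K and e ~ N(0, (1 - h2) * I); the non-causal part
    has unit total variance so causal_beta is in residual-sd units.
    """
    if truth.causal_variant_id not in panel.variant_ids:
        raise ValueError("causal variant absent from panel")
    rng = _rng(config, "phenotypes")
    if panel.groups is None:
        raise ValueError("panel carries no group labels")
    cult_ids = [a for a, g in zip(panel.accession_ids, panel.groups)
                if g in ("japonica", "indica")]
    if not cult_ids:
        raise ValueError("no cultivated accessions overlap the panel")
    sub = panel.subset_accessions(cult_ids)
    n = sub.n_accessions

    from .assoc import kinship_matrix
    K = kinship_matrix(sub.dosage_float())
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    u = U @ (np.sqrt(config.h2_polygenic * w) * rng.standard_normal(n))
    e = np.sqrt(1.0 - config.h2_polygenic) * rng.standard_normal(n)

    ci = sub.variant_ids.index(truth.causal_variant_id)
    g = sub.dosage_float()[ci]
    g = np.where(np.isnan(g), np.nanmean(g), g)
    y = config.causal_beta * g + u + e
    return pd.DataFrame({"accession": cult_ids, "trait": "GPAR-R", "value": y}) \
        .set_index("accession")


def simulate_bundle(config: SimConfig):
    """Generate the full input bundle and merged truth.

    Returns (expr, panel, geo, pheno, regulators, truth).
    """
    expr, truth_e = simulate_expression(config)
    panel, truth_g = simulate_genotypes(config)
    geo = simulate_geography(config)
    truth = truth_e.merge(truth_g)
    pheno = simulate_phenotypes(panel, truth, config)
    return expr, panel, geo, pheno, regulator_ids(config), truth


def write_bundle(config: SimConfig, outdir) -> dict:
    """Write every pipeline input to `outdir`; returns the path map."""
    from pathlib import Path
    from .genotypes import write_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr, panel, geo, pheno, regulators, truth = simulate_bundle(config)
    paths = {
        "counts": out / "expression_counts.tsv",
        "meta": out / "sample_metadata.tsv",
        "regulators": out / "regulators.txt",
        "vcf": out / "genotypes.vcf",
        "pheno": out / "phenotypes.tsv",
        "geo": out / "geography.tsv",
        "regions": out / "gene_regions.tsv",
        "truth": out / "truth.json",
    }
    expr.to_tsv(paths["counts"], paths["meta"])
    paths["regulators"].write_text("\n".join(regulators) + "\n")
    write_vcf(panel, paths["vcf"])
    pheno.to_csv(paths["pheno"], sep="\t")
    geo.to_csv(paths["geo"], sep="\t")
    with open(paths["regions"], "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\n")
        for gid, (c, s, e) in truth.gene_regions.items():
            fh.write(f"{gid}\t{c}\t{s}\t{e}\n")
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
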