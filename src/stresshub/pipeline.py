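"""End-to-end three-step hub-regulator screen.

Step 1 (transcriptome): stress DEGs -> ICA clusters -> per-cluster
GENIE3-style sub-networks with the NAC list as regulators -> hub ranking
by pooled degree. Step 2 (genetics): for each retained hub, a kinship
mixed-model association of the variants in its gene body + promoter
against each i-trait, keeping hubs with at least one variant below the
significance threshold (default 1e-4), plus the region LD triangle.
Step 3 (population / geography): windowed nucleotide diversity contrast
against the wild group (selective sweep) and the precipitation
distribution test on the best-associated variant. A regulator passes the
screen only when all three filters hold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import fit_null_reml, kinship_matrix, ld_r2, scan_region
from .expression import ExpressionMatrix, call_degs, zscore_rows
from .genotypes import GenotypePanel, read_vcf
from .grn import infer_grn, rank_hubs
from .ica import assign_clusters, fastica_decompose
from .popgen import precipitation_association, sweep_contrast, windowed_pi

__all__ = ["PipelineParams", "CandidateReport", "run_pipeline", "write_report",
           "run_from_config"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Thresholds and seeds for the three-step screen."""

    lfc_threshold: float = 1.0
    alpha: float = 0.05
    ica_k: int = 9
    ica_zcut: float = 2.0
    ica_seed: int = 0
    grn_trees: int = 1000
    grn_seed: int = 0
    top_e_per_target: int = 5
    hub_top_n: int = 9
    mlm_threshold: float = 1e-4
    maf_min: float = 0.05
    promoter_bp: int = 3000
    pi_window: int = 200
    sweep_ratio_cutoff: float = 0.5
    sweep_frac_windows: float = 0.5
    precip_alpha: float = 0.01
    wild_group: str = "O. ruf"
    cultivated_groups: tuple = ("japonica", "indica")
    report_all: bool = True

    def __post_init__(self):
        if not (0 < self.alpha <= 1 and 0 < self.mlm_threshold <= 1
                and 0 < self.precip_alpha <= 1):
            raise ValueError("significance thresholds must lie in (0, 1]")
        if self.pi_window < 1 or self.promoter_bp < 0:
            raise ValueError("window/promoter sizes must be positive")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")


@dataclass
class CandidateReport:
    """Per-regulator record of the three filters."""

    regulator: str
    hub_degree: int = 0
    hub_rank: int | None = None
    hub_retained: bool = False
    n_significant: dict = field(default_factory=dict)   # trait -> count
    best_p: dict = field(default_factory=dict)          # trait -> min p
    assoc_pass: bool = False
    sweep: dict = field(default_factory=dict)           # group -> flag/None
    sweep_pass: bool = False
    precip_p: float | None = None
    precip_flag: bool = False
    focal_variant: str | None = None
    final_pass: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(expr: ExpressionMatrix, regulators, panel: GenotypePanel,
                 pheno: pd.DataFrame, geo: pd.DataFrame, gene_regions: dict,
                 params: PipelineParams = PipelineParams(),
                 outdir=None):
    """Run the three-step screen; returns (reports, provenance).

    Parameters
    ----------
    expr : ExpressionMatrix
    regulators : sequence of regulator (NAC) gene ids
    panel : GenotypePanel with population group labels
    pheno : DataFrame indexed by accession with columns trait, value
        (long form; several traits allowed)
    geo : DataFrame indexed by accession with columns longitude, latitude,
        precip_mm, group
    gene_regions : regulator id -> (chrom, start, end) gene body,
        1-based inclusive
    outdir : optional directory for per-step artifacts (DEG table,
        cluster assignments, edge list, scans, LD, diversity profiles).
    """
    regulators = list(dict.fromkeys(regulators))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "version": __version__,
        "params": dataclasses.asdict(params),
        "n_regulators": len(regulators),
    }
    provenance["config_hash"] = _config_hash(provenance["params"])
    if not regulators:
        log.warning("empty regulator list: nothing to screen")
        return [], provenance

    # ---- step 1: DEGs -> ICA clusters -> sub-GRNs -> hub degree ----
    conditions = [c for c in expr.metadata["condition"].unique() if c != "control"]
    deg_tables = [call_degs(expr, (c, "control"), params.lfc_threshold,
                            params.alpha) for c in conditions]
    degs = pd.concat(deg_tables, ignore_index=True) if deg_tables else pd.DataFrame()
    deg_genes = sorted(set(degs["gene_id"])) if len(degs) else []
    log.info("step 1: %d DEGs across %d contrasts", len(deg_genes), len(conditions))
    if out is not None and len(degs):
        degs.to_csv(out / "degs.tsv", sep="\t", index=False)

    z = pd.DataFrame(zscore_rows(np.log2(expr.tpm + 1.0)),
                     index=expr.gene_ids, columns=expr.sample_ids)
    reports = {r: CandidateReport(regulator=r) for r in regulators}

    edges = pd.DataFrame(columns=["cluster", "regulator", "target", "importance"])
    if len(deg_genes) >= 2:
        k = min(params.ica_k, len(deg_genes) - 1, len(expr.sample_ids) - 1)
        model = fastica_decompose(z.loc[deg_genes], K=max(k, 1),
                                  seed=params.ica_seed)
        clusters = assign_clusters(model, z_cut=params.ica_zcut)
        if out is not None:
            model.loadings_frame().to_csv(out / "ica_loadings.tsv", sep="\t")
            clusters.to_frame().to_csv(out / "ica_clusters.tsv", sep="\t")
        regs_in_expr = sorted(set(regulators) & set(expr.gene_ids))
        edge_parts = []
        for lab in sorted(clusters.dropna().unique()):
            members = list(clusters.index[clusters == lab])
            targets = [g for g in members]
            if not targets or len(regs_in_expr) < 2:
                continue
            sub = z.loc[sorted(set(regs_in_expr) | set(members))]
            edge_parts.append(infer_grn(sub, regs_in_expr, targets=targets,
                                        n_trees=params.grn_trees,
                                        seed=params.grn_seed,
                                        cluster=int(lab)))
        if edge_parts:
            edges = pd.concat(edge_parts, ignore_index=True)
    hubs = rank_hubs(edges, top_e_per_target=params.top_e_per_target)
    if out is not None:
        edges.to_csv(out / "grn_edges.tsv", sep="\t", index=False)
        hubs.to_csv(out / "hub_table.tsv", sep="\t", index=False)
    for _, row in hubs.iterrows():
        r = row["regulator"]
        if r in reports:
            reports[r].hub_degree = int(row["degree"])
            reports[r].hub_rank = int(row["rank"])
            reports[r].hub_retained = (row["rank"] <= params.hub_top_n
                                       and row["degree"] >= 1)
    retained = [r for r in regulators if reports[r].hub_retained]
    log.info("step 1: retained hubs %s", retained)

    # ---- step 2 setup: phenotype/kinship alignment ----
    traits = sorted(pheno["trait"].unique())
    acc_assoc = [a for a in panel.accession_ids if a in set(pheno.index)]
    nulls, ys = {}, {}
    if len(acc_assoc) >= 10:
        sub_assoc = panel.subset_accessions(acc_assoc)
        K = kinship_matrix(sub_assoc.dosage_float())
        for trait in traits:
            tv = pheno[pheno["trait"] == trait]["value"]
            y = tv.reindex(acc_assoc).to_numpy(dtype=float)
            okn = ~np.isnan(y)
            if okn.sum() < 10:
                continue
            ys[trait] = (y[okn], np.where(okn)[0])
            Ksub = K[np.ix_(ys[trait][1], ys[trait][1])]
            nulls[trait] = fit_null_reml(ys[trait][0], Ksub)
    else:
        log.warning("fewer than 10 phenotyped accessions overlap the panel; "
                    "association step skipped")
        sub_assoc, K = None, None

    todo = regulators if params.report_all else retained
    geo_precip = geo["precip_mm"] if "precip_mm" in geo else None

    for reg in todo:
        rep = reports[reg]
        if reg not in gene_regions:
            log.info("no gene region for %s; genetic filters skipped", reg)
            continue
        chrom, gstart, gend = gene_regions[reg]
        rstart = max(1, gstart - params.promoter_bp)
        region_panel = panel.subset_region(chrom, rstart, gend)

        # step 2: region-based MLM association + LD
        scans = {}
        if nulls and region_panel.n_variants:
            assoc_region = sub_assoc.subset_region(chrom, rstart, gend)
            for trait, null in nulls.items():
                yv, okidx = ys[trait]
                p_use = assoc_region.subset_accessions(
                    [acc_assoc[i] for i in okidx])
                scan = scan_region(yv, p_use,
                                   K=K[np.ix_(okidx, okidx)], null=null,
                                   threshold=params.mlm_threshold,
                                   maf_min=params.maf_min)
                scans[trait] = scan
                rep.n_significant[trait] = int(scan["significant"].sum())
                rep.best_p[trait] = (float(scan["pvalue"].min())
                                     if len(scan) else None)
                if out is not None:
                    scan.to_csv(out / f"scan_{reg}_{trait}.tsv", sep="\t",
                                index=False)
            if out is not None and assoc_region.n_variants >= 2:
                ld_r2(assoc_region).to_csv(out / f"ld_{reg}.tsv", sep="\t")
        rep.assoc_pass = any(v >= 1 for v in rep.n_significant.values())

        # step 3: sweep contrast + precipitation distribution
        region = (chrom, rstart, gend)
        try:
            wild = windowed_pi(panel, group=params.wild_group, region=region,
                               window=params.pi_window)
        except ValueError:
            wild = None
        if wild is not None:
            for cg in params.cultivated_groups:
                try:
                    cult = windowed_pi(panel, group=cg, region=region,
                                       window=params.pi_window)
                except ValueError:
                    continue
                call = sweep_contrast(wild, cult,
                                      ratio_cutoff=params.sweep_ratio_cutoff,
                                      frac_windows=params.sweep_frac_windows)
                rep.sweep[cg] = call.flag
        rep.sweep_pass = any(v is True for v in rep.sweep.values())

        best = None
        for trait, scan in scans.items():
            poly = scan[scan["maf"] > 0]
            if len(poly):
                cand = poly.loc[poly["pvalue"].idxmin()]
                if best is None or cand["pvalue"] < best["pvalue"]:
                    best = cand
        if best is not None and geo_precip is not None:
            rep.focal_variant = str(best["variant_id"])
            vi = panel.variant_ids.index(rep.focal_variant)
            dos = panel.dosage_float()[vi]
            precip = geo_precip.reindex(panel.accession_ids).to_numpy(dtype=float)
            okg = ~np.isnan(dos) & ~np.isnan(precip)
            carrier = dos[okg] > 0
            if 2 <= carrier.sum() and 2 <= (~carrier).sum():
                res = precipitation_association(precip[okg], carrier,
                                                alpha=params.precip_alpha)
                rep.precip_p = res.pvalue
                rep.precip_flag = res.flag

        rep.final_pass = (rep.hub_retained and rep.assoc_pass
                          and rep.sweep_pass and rep.precip_flag)

    order = sorted(regulators,
                   key=lambda r: (-int(reports[r].final_pass),
                                  -reports[r].hub_degree, r))
    return [reports[r] for r in order], provenance


def write_report(reports, provenance, outdir) -> dict:
    """Write report.json + report.tsv; returns the path map.

    Output is timestamp-free and key-sorted so identical runs produce
    byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": provenance,
               "candidates": [r.to_dict() for r in reports]}
    jpath = out / "report.json"
    with open(jpath, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    rows = []
    for r in reports:
        rows.append({
            "regulator": r.regulator,
            "hub_degree": r.hub_degree,
            "hub_rank": r.hub_rank,
            "hub_retained": r.hub_retained,
            "n_significant": sum(r.n_significant.values()),
            "best_p": min([v for v in r.best_p.values() if v is not None],
                          default=None),
            "sweep_pass": r.sweep_pass,
            "precip_flag": r.precip_flag,
            "final_pass": r.final_pass,
        })
    tpath = out / "report.tsv"
    pd.DataFrame(rows).to_csv(tpath, sep="\t", index=False)
    return {"json": str(jpath), "tsv": str(tpath)}


def _load_gene_regions(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {row["gene_id"]: (row["chrom"], int(row["start"]), int(row["end"]))
            for _, row in df.iterrows()}


def run_from_config(config_path, outdir=None):
    """Run the screen from a YAML config file (paths + parameter blocks)."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    inputs = cfg["inputs"]
    params = PipelineParams(**cfg.get("params", {}))
    outdir = outdir or cfg.get("outdir", "stresshub_out")

    expr = ExpressionMatrix.from_tsv(inputs["counts"], inputs["meta"])
    regulators = [ln.strip() for ln in open(inputs["regulators"])
                  if ln.strip()]
    geo = pd.read_csv(inputs["geo"], sep="\t", index_col=0)
    groups = dict(zip(geo.index, geo["group"]))
    panel = read_vcf(inputs["vcf"], groups=groups)
    pheno = pd.read_csv(inputs["pheno"], sep="\t", index_col=0)
    gene_regions = _load_gene_regions(inputs["regions"])

    reports, provenance = run_pipeline(expr, regulators, panel, pheno, geo,
                                       gene_regions, params, outdir=outdir)
    provenance["config_file"] = str(config_path)
    paths = write_report(reports, provenance, outdir)
    with open(Path(outdir) / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return reports, provenance, paths
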