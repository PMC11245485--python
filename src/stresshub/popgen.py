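"""Windowed nucleotide diversity, sweep contrast, and geography statistics.

Nucleotide diversity per polymorphic site is the unbiased expected
heterozygosity ``(n/(n-1)) * 2 p (1-p)`` with n the number of non-missing
alleles (two per diploid), which equals the average pairwise difference
among sampled alleles. Window pi divides the per-site sum by the window
length in bp (monomorphic positions contribute zero), the convention of
windowed-pi VCF tools; the per-variant-site average is reported alongside.

The sweep contrast flags a gene region when the cultivated-group pi falls
below `ratio_cutoff` times the wild-group pi in at least `frac_windows`
of the informative windows. Genotype-class phenotype differences and the
precipitation-distribution association use two-sided Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypePanel

__all__ = ["windowed_pi", "sweep_contrast", "SweepCall", "genotype_group_test",
           "zscore_normalize", "precipitation_association"]


def _site_pi(dosage_row: np.ndarray) -> float:
    """Unbiased per-site diversity from one variant's diploid dosages."""
    d = dosage_row[~np.isnan(dosage_row)]
    n = 2 * d.size
    if n < 2:
        return 0.0
    p = d.sum() / n
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return (n / (n - 1)) * 2.0 * p * (1.0 - p)


def windowed_pi(panel: GenotypePanel, group: str | None = None,
                region: tuple | None = None, window: int = 200) -> pd.DataFrame:
    """Nucleotide diversity in non-overlapping windows (default 200 bp).

    Windows tile the region from its start: [start, start+window-1], ...
    (1-based inclusive). `region` is (chrom, start, end); by default the
    panel's full span on its single chromosome. With `group` given, only
    that population's accessions enter the computation.

    Returns a DataFrame (chrom, start, end, group, pi, pi_per_site,
    n_sites) where `pi` is the length-normalised window diversity and
    `pi_per_site` the average over variant sites only.
    """
    sub = panel if group is None else panel.subset_group(group)
    if group is not None and sub.n_accessions < 2:
        raise ValueError(f"group {group!r} has < 2 accessions")
    if region is None:
        chroms = np.unique(panel.chrom)
        if len(chroms) != 1:
            raise ValueError("multi-chromosome panel: pass region explicitly")
        region = (chroms[0], 1, int(panel.pos.max()))
    chrom, start, end = region
    sub = sub.subset_region(chrom, start, end)
    d = sub.dosage_float()

    rows = []
    w_start = start
    while w_start <= end:
        w_end = min(w_start + window - 1, end)
        m = (sub.pos >= w_start) & (sub.pos <= w_end)
        idx = np.where(m)[0]
        site_pis = [_site_pi(d[i]) for i in idx]
        n_seg = sum(1 for v in site_pis if v > 0)
        total = float(sum(site_pis))
        length = w_end - w_start + 1
        rows.append({
            "chrom": chrom, "start": w_start, "end": w_end,
            "group": group if group is not None else "all",
            "pi": total / length,
            "pi_per_site": total / n_seg if n_seg else 0.0,
            "n_sites": n_seg,
        })
        w_start += window
    return pd.DataFrame(rows)


@dataclass
class SweepCall:
    """Wild vs cultivated diversity contrast over one gene region."""

    group: str
    mean_pi_wild: float
    mean_pi_cult: float
    ratio: float
    n_informative: int
    n_low: int
    flag: bool | None             # None: indeterminate (no informative windows)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "mean_pi_wild": self.mean_pi_wild,
            "mean_pi_cult": self.mean_pi_cult,
            "ratio": self.ratio,
            "n_informative": self.n_informative,
            "n_low": self.n_low,
            "flag": self.flag,
        }


def sweep_contrast(wild_profile: pd.DataFrame, cult_profile: pd.DataFrame,
                   ratio_cutoff: float = 0.5,
                   frac_windows: float = 0.5) -> SweepCall:
    """Flag a selective sweep from matched wild / cultivated pi profiles.

    Both profiles must tile identical windows. A window is informative
    when the wild pi is positive; the flag is true when the cultivated/wild
    pi ratio is below `ratio_cutoff` in at least `frac_windows` of the
    informative windows. With no informative window the flag is
    indeterminate (None).
    """
    for col in ("start", "end"):
        if not np.array_equal(wild_profile[col].to_numpy(),
                              cult_profile[col].to_numpy()):
            raise ValueError("profiles computed on different windows")
    pw = wild_profile["pi"].to_numpy(dtype=float)
    pc = cult_profile["pi"].to_numpy(dtype=float)
    informative = pw > 0
    n_inf = int(informative.sum())
    group = str(cult_profile["group"].iloc[0]) if len(cult_profile) else "cultivated"
    mean_w = float(pw.mean()) if len(pw) else 0.0
    mean_c = float(pc.mean()) if len(pc) else 0.0
    ratio = mean_c / mean_w if mean_w > 0 else np.nan
    if n_inf == 0:
        return SweepCall(group, mean_w, mean_c, ratio, 0, 0, None)
    low = (pc[informative] / pw[informative]) < ratio_cutoff
    n_low = int(low.sum())
    flag = (n_low / n_inf) >= frac_windows
    return SweepCall(group, mean_w, mean_c, ratio, n_inf, n_low, flag)


def genotype_group_test(values_a, values_b, equal_var: bool = False):
    """Two-sided two-sample t-test between genotype classes (Welch default).

    Returns (t, pvalue, mean_a, mean_b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each genotype class needs >= 2 accessions")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), float(a.mean()), float(b.mean())


def zscore_normalize(values) -> np.ndarray:
    """Z-scores with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: Z-scores undefined")
    return (x - x.mean()) / sd


@dataclass
class PrecipAssociation:
    mean_precip_carrier: float
    mean_precip_noncarrier: float
    t: float
    pvalue: float
    r_pointbiserial: float
    n_carrier: int
    n_noncarrier: int
    flag: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "mean_precip_carrier", "mean_precip_noncarrier", "t", "pvalue",
            "r_pointbiserial", "n_carrier", "n_noncarrier", "flag")}


def precipitation_association(precip, carrier, alpha: float = 0.01) -> PrecipAssociation:
    """Test whether a variant's allele classes differ in mean precipitation.

    `carrier` is a boolean vector (allele class per accession, e.g.
    InDel+ / InDel-), `precip` the accessions' mean precipitation (mm).
    Performs a Welch t-test plus the point-biserial correlation; the
    "precipitation-related distribution" flag is p < alpha.
    """
    precip = np.asarray(precip, dtype=float)
    carrier = np.asarray(carrier, dtype=bool)
    if precip.shape != carrier.shape:
        raise ValueError("precip and carrier must align")
    ok = ~np.isnan(precip)
    if ok.sum() < 0.5 * precip.size:
        raise ValueError("precipitation missing for > 50% of accessions")
    precip, carrier = precip[ok], carrier[ok]
    a, b = precip[carrier], precip[~carrier]
    if a.size < 2 or b.size < 2:
        raise ValueError("each allele class needs >= 2 accessions with precipitation")
    t, p, mean_a, mean_b = genotype_group_test(a, b)
    r, _ = stats.pointbiserialr(carrier.astype(int), precip)
    return PrecipAssociation(
        mean_precip_carrier=mean_a, mean_precip_noncarrier=mean_b,
        t=t, pvalue=p, r_pointbiserial=float(r),
        n_carrier=int(a.size), n_noncarrier=int(b.size),
        flag=bool(p < alpha))
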