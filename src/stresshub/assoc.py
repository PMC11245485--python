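"""Kinship mixed-model association and linkage disequilibrium.

The model is the standard single-trait animal model

    y = X b + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with K a VanRaden genomic kinship. The null variance ratio
delta = se2 / sg2 is profiled by REML on the eigenbasis of S K S
(S the projection off the fixed effects) — one eigendecomposition and a
1-D optimisation of delta over log-delta in [-10, 10]. Per-variant tests
then use the fixed-ratio (EMMAX / P3D) approximation: rotate y, X and the
genotype by the eigenbasis of K, weight by (lambda_i + delta)^(-1/2), and
F-test the genotype term with (1, n - p - 1) degrees of freedom. An exact
mode refits delta per variant for oracle comparisons.

``KinshipMLM`` wraps the null fit as a model object whose ``fit()``
returns a results object with variance components, the REML
log-likelihood and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypePanel

__all__ = ["kinship_matrix", "KinshipMLM", "KinshipMLMResults",
           "fit_null_reml", "scan_region", "ld_r2"]


def _impute_dosage(d: np.ndarray) -> np.ndarray:
    """Mean-impute missing (NaN) dosages per variant row."""
    d = np.array(d, dtype=float)
    for i in range(d.shape[0]):
        m = np.isnan(d[i])
        if m.any():
            fill = np.nanmean(d[i]) if not m.all() else 0.0
            d[i, m] = fill
    return d


def kinship_matrix(dosage, accession_ids=None) -> np.ndarray:
    """VanRaden genomic relationship matrix from a variants x accessions dosage.

    Dosages are centred by twice the allele frequency and the cross-product
    is scaled by 2 * sum p(1-p); the diagonal is ~1 plus inbreeding. Missing
    genotypes are mean-imputed per variant; monomorphic variants are
    dropped.
    """
    d = np.asarray(dosage, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2:
        raise ValueError("need a variants x accessions matrix with >= 2 accessions")
    d = _impute_dosage(d)
    p = d.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic variants for kinship")
    W = d[poly] - 2.0 * p[poly, None]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = W.T @ W / denom
    K = (K + K.T) / 2.0
    if accession_ids is not None:
        return pd.DataFrame(K, index=accession_ids, columns=accession_ids)
    return K


@dataclass
class KinshipMLMResults:
    """Variance components and REML diagnostics from a null-model fit."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float
    beta: np.ndarray
    n: int
    p: int
    eigenvalues: np.ndarray       # eigenvalues of K (full basis, cached)
    eigenvectors: np.ndarray
    xi: np.ndarray                # eigenvalues of S K S used by REML
    eta: np.ndarray               # rotated residual contrasts

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan

    def summary(self) -> str:
        lines = [
            "Kinship mixed linear model (REML, spectral profile of delta)",
            "=" * 60,
            f"n accessions        {self.n}",
            f"fixed effects (p)   {self.p}",
            f"sigma_g^2           {self.sigma_g2:.6g}",
            f"sigma_e^2           {self.sigma_e2:.6g}",
            f"delta = se2/sg2     {self.delta:.6g}",
            f"h2 = sg2/(sg2+se2)  {self.heritability:.4f}",
            f"REML log-likelihood {self.loglik:.4f}",
        ]
        return "\n".join(lines)


class KinshipMLM:
    """Mixed linear model y = Xb + u + e with cov(u) = sg2 * K."""

    def __init__(self, y, K, covariates=None):
        y = np.asarray(y, dtype=float).ravel()
        K = np.asarray(K, dtype=float)
        n = y.size
        if K.shape != (n, n):
            raise ValueError("K must be n x n aligned with y")
        if np.any(~np.isfinite(y)):
            raise ValueError("y must be complete (no NaN)")
        if n < 10:
            raise ValueError("need >= 10 accessions")
        if np.max(np.abs(K - K.T)) > 1e-10:
            raise ValueError("K must be symmetric")
        self.y, self.K, self.n = y, (K + K.T) / 2.0, n
        if covariates is None:
            X = np.ones((n, 1))
        else:
            X = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        self.X = X
        self.p = X.shape[1]

    def fit(self, log_delta_bounds=(-10.0, 10.0), grid: int = 101) -> KinshipMLMResults:
        y, X, K, n, p = self.y, self.X, self.K, self.n, self.p
        w_k, U_k = np.linalg.eigh(K)
        if w_k.min() < -1e-8:
            K = K + (1e-8 - w_k.min()) * np.eye(n)     # jitter
            w_k, U_k = np.linalg.eigh(K)
            if w_k.min() < -1e-8:
                raise ValueError("kinship matrix not PSD after jitter")
        w_k = np.clip(w_k, 0.0, None)

        # eigenbasis of S K S restricted to the residual space
        Q, _ = np.linalg.qr(X)
        SKS = K - Q @ (Q.T @ K) - (K @ Q) @ Q.T + Q @ (Q.T @ K @ Q) @ Q.T
        SKS = (SKS + SKS.T) / 2.0
        w_s, U_s = np.linalg.eigh(SKS)
        order = np.argsort(w_s)[::-1][: n - p]
        xi = np.clip(w_s[order], 0.0, None)
        Us = U_s[:, order]
        eta = Us.T @ y
        eta2 = eta ** 2
        m = n - p

        def neg_restricted_ll(log_delta):
            d = np.exp(log_delta)
            denom = xi + d
            R = np.sum(eta2 / denom)
            if not np.isfinite(R) or R <= 0:
                return np.inf
            return 0.5 * (m * np.log(2.0 * np.pi * R / m) + m
                          + np.sum(np.log(denom)))

        lo, hi = log_delta_bounds
        gridpts = np.linspace(lo, hi, grid)
        vals = np.array([neg_restricted_ll(g) for g in gridpts])
        if not np.isfinite(vals).any():
            raise ValueError("non-finite REML likelihood over the delta grid")
        i = int(np.argmin(vals))
        a = gridpts[max(i - 1, 0)]
        b = gridpts[min(i + 1, grid - 1)]
        if a < b:
            res = optimize.minimize_scalar(neg_restricted_ll, bounds=(a, b),
                                           method="bounded",
                                           options={"xatol": 1e-8})
            best = res.x if res.fun <= vals[i] else gridpts[i]
        else:
            best = gridpts[i]
        delta = float(np.exp(best))
        R = float(np.sum(eta2 / (xi + delta)))
        sigma_g2 = R / m
        sigma_e2 = delta * sigma_g2
        loglik = -neg_restricted_ll(best)
        if not np.isfinite(loglik):
            raise ValueError("non-finite REML log-likelihood at the optimum")

        # GLS fixed effects at the fitted ratio
        weights = 1.0 / np.sqrt(w_k + delta)
        Xs = (U_k.T @ X) * weights[:, None]
        ys = (U_k.T @ y) * weights
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        return KinshipMLMResults(
            sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta, loglik=loglik,
            beta=beta, n=n, p=p, eigenvalues=w_k, eigenvectors=U_k,
            xi=xi, eta=eta)


def fit_null_reml(y, K, covariates=None) -> KinshipMLMResults:
    """Fit the no-genotype null model by spectral REML (EMMA profile)."""
    return KinshipMLM(y, K, covariates=covariates).fit()


def _region_dosage(panel_or_dosage):
    if isinstance(panel_or_dosage, GenotypePanel):
        p = panel_or_dosage
        return (p.dosage_float(), list(p.variant_ids), list(p.chrom), list(p.pos))
    d = np.asarray(panel_or_dosage, dtype=float)
    ids = [f"v{i + 1}" for i in range(d.shape[0])]
    return d, ids, ["."] * d.shape[0], [0] * d.shape[0]


def scan_region(y, panel, K=None, null: KinshipMLMResults | None = None,
                threshold: float = 1e-4, maf_min: float = 0.05,
                covariates=None, exact: bool = False) -> pd.DataFrame:
    """Per-variant mixed-model association over a genotype region.

    Uses the EMMAX fixed-ratio approximation by default: the variance
    ratio fitted once on the null model is reused for every variant and
    the genotype term is F-tested with (1, n - p - 1) df. Monomorphic
    variants are reported with p = 1; variants with 0 < MAF < `maf_min`
    are dropped.

    Returns a DataFrame (variant_id, chrom, pos, maf, beta, F, pvalue,
    significant) with the significance flag set by `threshold`.
    """
    y = np.asarray(y, dtype=float).ravel()
    d, ids, chrom, pos = _region_dosage(panel)
    n = y.size
    if d.shape[1] != n:
        raise ValueError("genotype accessions do not match phenotype length")
    if K is None:
        K = np.eye(n)
    K = np.asarray(K, dtype=float)
    if null is None:
        null = fit_null_reml(y, K, covariates=covariates)

    d = _impute_dosage(d)
    p_alt = d.mean(axis=1) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    mono = maf == 0
    keep = mono | (maf >= maf_min)

    delta = null.delta
    w, U = null.eigenvalues, null.eigenvectors
    weights = 1.0 / np.sqrt(w + delta)
    X = np.ones((n, 1)) if covariates is None else \
        np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    p_fixed = X.shape[1]
    ys = (U.T @ y) * weights
    Xs = (U.T @ X) * weights[:, None]
    Q, _ = np.linalg.qr(Xs)
    ry = ys - Q @ (Q.T @ ys)
    rss0 = float(ry @ ry)
    df2 = n - p_fixed - 1

    rows = []
    for i in np.where(keep)[0]:
        if mono[i]:
            rows.append((ids[i], chrom[i], pos[i], 0.0, 0.0, 0.0, 1.0))
            continue
        if exact:
            refit = KinshipMLM(y, K, covariates=_augment(covariates, d[i])).fit()
            delta_i = refit.delta
            weights_i = 1.0 / np.sqrt(w + delta_i)
            ys_i = (U.T @ y) * weights_i
            Xs_i = (U.T @ X) * weights_i[:, None]
            Qi, _ = np.linalg.qr(Xs_i)
            ry_i = ys_i - Qi @ (Qi.T @ ys_i)
            rss0_i = float(ry_i @ ry_i)
            gs = (U.T @ d[i]) * weights_i
            rg = gs - Qi @ (Qi.T @ gs)
            beta, F, pv = _marginal_f(ry_i, rg, rss0_i, df2)
        else:
            gs = (U.T @ d[i]) * weights
            rg = gs - Q @ (Q.T @ gs)
            beta, F, pv = _marginal_f(ry, rg, rss0, df2)
        rows.append((ids[i], chrom[i], pos[i], float(maf[i]), beta, F, pv))
    out = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "maf",
                                      "beta", "F", "pvalue"])
    out["significant"] = out["pvalue"] < threshold
    return out


def _augment(covariates, g):
    if covariates is None:
        return g[:, None]
    return np.column_stack([np.asarray(covariates, dtype=float), g])


def _marginal_f(ry, rg, rss0, df2):
    gg = float(rg @ rg)
    if gg <= 1e-12 or df2 <= 0:
        return 0.0, 0.0, 1.0
    beta = float(rg @ ry) / gg
    rss1 = max(rss0 - beta * beta * gg, 0.0)
    if rss1 <= 0:
        return beta, np.inf, np.nextafter(0, 1)
    F = (rss0 - rss1) * df2 / rss1
    return beta, float(F), float(stats.f.sf(F, 1, df2))


def ld_r2(panel) -> pd.DataFrame:
    """Pairwise composite LD: squared Pearson correlation of dosage vectors.

    Missing genotypes are dropped pairwise; monomorphic variants get NaN
    rows/columns (diagonal 1 only for polymorphic variants).
    """
    d, ids, _, _ = _region_dosage(panel)
    m = d.shape[0]
    if m < 2:
        raise ValueError("need >= 2 variants for LD")
    r2 = np.full((m, m), np.nan)
    sds = [np.nanstd(d[i]) for i in range(m)]
    for i in range(m):
        if sds[i] > 0:
            r2[i, i] = 1.0
        for j in range(i + 1, m):
            ok = ~np.isnan(d[i]) & ~np.isnan(d[j])
            if ok.sum() < 2:
                continue
            a, b = d[i, ok], d[j, ok]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return pd.DataFrame(r2, index=ids, columns=ids)
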