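"""Independent component analysis of the stress-DEG expression submatrix.

The DEG x sample matrix (gene-wise Z-transformed expression) is centred
and whitened by eigendecomposition of its sample-sample covariance, then
unmixed by fixed-point FastICA with the logcosh contrast (symmetric
updates, with a deflation fallback when the symmetric iteration stalls).
Genes act as observations, so the independent components live in gene
space: the ``loadings`` (genes x K, unit-norm columns) are sparse,
super-Gaussian module indicators, and the ``sources`` (K x samples) are
the corresponding sample-space activity patterns. Components are ordered
by explained variance and sign-fixed so each column's largest-magnitude
loading is positive, making the decomposition reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = ["ICAModel", "ICAConvergenceError", "fastica_decompose", "assign_clusters"]


class ICAConvergenceError(RuntimeError):
    """FastICA failed to converge after all restarts; carries diagnostics."""

    def __init__(self, attempts):
        self.attempts = attempts
        super().__init__(
            "FastICA did not converge; attempts (algorithm, seed, n_iter): "
            + ", ".join(map(str, attempts)))


@dataclass
class ICAModel:
    n_components: int
    sources: np.ndarray          # K x samples
    loadings: np.ndarray         # genes x K, unit-norm columns
    gene_ids: list
    sample_ids: list
    whitened: np.ndarray         # genes x K, identity covariance
    col_means: np.ndarray        # per-sample centring offsets
    convergence: dict = field(default_factory=dict)
    seed: int = 0
    cluster_of: pd.Series | None = None

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"IC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.loadings, index=self.gene_ids, columns=cols)

    def sources_frame(self) -> pd.DataFrame:
        rows = [f"IC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.sources, index=rows, columns=self.sample_ids)


def _whiten(X: np.ndarray, K: int):
    """Centre columns and project onto K whitened directions.

    Returns (X_white genes x K with identity covariance, col_means,
    projection matrix samples x K).
    """
    mu = X.mean(axis=0)
    Xc = X - mu
    n = X.shape[0]
    cov = Xc.T @ Xc / (n - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:K]
    w, V = w[order], V[:, order]
    if w[-1] <= 1e-12 * max(w[0], 1.0):
        raise ValueError(f"covariance rank < K={K}; reduce the component count")
    proj = V / np.sqrt(w)
    return Xc @ proj, mu, proj


def fastica_decompose(X, K: int = 9, seed: int = 0, tol: float = 1e-6,
                      max_iter: int = 500, n_restarts: int = 3) -> ICAModel:
    """Fit a K-component ICA model to a genes x samples matrix.

    X should be gene-wise Z-transformed expression (a DataFrame keeps the
    ids; a bare array gets positional ids). K defaults to 9, the cluster
    count used for the stress-DEG grouping.
    """
    if isinstance(X, pd.DataFrame):
        gene_ids, sample_ids = list(X.index), list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        gene_ids = [f"g{i}" for i in range(arr.shape[0])]
        sample_ids = [f"s{j}" for j in range(arr.shape[1])]
    n_genes, n_samples = arr.shape
    if K > min(n_genes, n_samples):
        raise ValueError(f"K={K} exceeds matrix rank bound {min(arr.shape)}")

    Xw, mu, proj = _whiten(arr, K)

    attempts = []
    S = None
    for algorithm in ("parallel", "deflation"):
        for restart in range(n_restarts):
            ica = FastICA(n_components=K, whiten=False, fun="logcosh",
                          algorithm=algorithm, tol=tol, max_iter=max_iter,
                          random_state=seed + 1000 * restart)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                S_try = ica.fit_transform(Xw)
                failed = any(issubclass(w.category, ConvergenceWarning)
                             for w in caught)
            attempts.append((algorithm, seed + 1000 * restart, int(ica.n_iter_)))
            if not failed:
                S = S_try
                break
        if S is not None:
            break
    if S is None:
        raise ICAConvergenceError(attempts)

    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    loadings = S / norms

    # order by energy captured in the whitened space, then canonicalize sign
    energy = norms ** 2
    order = np.argsort(energy)[::-1]
    loadings = loadings[:, order]
    sign = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(K)])
    sign[sign == 0] = 1.0
    loadings *= sign

    sources, *_ = np.linalg.lstsq(loadings, arr - mu, rcond=None)
    return ICAModel(
        n_components=K,
        sources=sources,
        loadings=loadings,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        whitened=Xw,
        col_means=mu,
        convergence={"attempts": attempts, "tol": tol, "max_iter": max_iter},
        seed=seed,
    )


def assign_clusters(model: ICAModel, z_cut: float = 2.0) -> pd.Series:
    """Assign each gene to its dominant component, or leave it unassigned.

    A gene goes to cluster k* = argmax_k |loading[g, k]| (ties to the
    lowest k) provided |loading[g, k*]|, standardised within column k*,
    exceeds `z_cut`; otherwise it gets pd.NA. Cluster labels are 1..K.
    """
    A = np.abs(model.loadings)
    k_star = A.argmax(axis=1)                       # argmax breaks ties low
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (A[np.arange(A.shape[0]), k_star] - mu[k_star]) / sd[k_star]
    labels = pd.array(np.where(z > z_cut, k_star + 1, -1), dtype="Int64")
    labels[labels == -1] = pd.NA
    out = pd.Series(labels, index=model.gene_ids, name="cluster")
    model.cluster_of = out
    return out
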