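"""Regulator-restricted network inference and hub ranking (GENIE3 scheme).

For every target gene, a random-forest regression of its (Z-transformed)
expression on the candidate regulators is fitted; the importance of edge
regulator -> target is the total impurity reduction attributed to that
regulator, normalised per target to sum to one. Edges are pooled across
targets (and clusters), a retention rule keeps each target's strongest
regulators, and hub regulators are ranked by out-degree over retained
edges.
"""

from __future__ import annotations

import logging
import math
import zlib

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = ["infer_grn", "rank_hubs"]

log = logging.getLogger(__name__)


def _target_seed(seed: int, target: str) -> int:
    return (zlib.crc32(target.encode()) ^ (seed * 2654435761)) % (2 ** 31)


def infer_grn(expr, regulators, targets=None, n_trees: int = 1000,
              seed: int = 0, cluster: str | int = "all") -> pd.DataFrame:
    """Score regulator -> target edges by tree-ensemble importance.

    Parameters
    ----------
    expr : DataFrame, genes x samples
        Gene-wise Z-transformed expression; must contain the regulators
        (and targets, if given) in its index.
    regulators : sequence of gene ids
        Candidate regulators (the NAC list). Sorted internally so the
        result is invariant to the order passed in.
    targets : sequence of gene ids, optional
        Genes to regress (default: every gene in `expr`). Regulators may
        be targets of other regulators; self-edges are never emitted.
    n_trees : int
        Trees per forest (original GENIE3 default 1000); mtry is
        ceil(sqrt(R)) over R candidate regulators.
    cluster : label recorded on every edge row.

    Returns a DataFrame with columns cluster, regulator, target,
    importance; importances sum to 1 per non-constant target.
    """
    if not isinstance(expr, pd.DataFrame):
        raise TypeError("expr must be a genes x samples DataFrame")
    regs = sorted(set(regulators) & set(expr.index))
    if len(regs) < 2:
        raise ValueError("need >= 2 regulators present in the expression matrix")
    if expr.shape[1] < 5:
        raise ValueError("need >= 5 samples for forest regression")
    if targets is None:
        targets = list(expr.index)
    missing = set(targets) - set(expr.index)
    if missing:
        raise KeyError(f"targets absent from expression matrix: {sorted(missing)[:5]}")

    X_all = expr.loc[regs].to_numpy(dtype=float).T      # samples x regulators
    rows = []
    for target in targets:
        y = expr.loc[target].to_numpy(dtype=float)
        if np.std(y) == 0:
            log.info("target %s constant; skipped", target)
            continue
        feat_idx = [j for j, r in enumerate(regs) if r != target]
        if len(feat_idx) < 1:
            continue
        X = X_all[:, feat_idx]
        mtry = min(len(feat_idx), math.ceil(math.sqrt(len(feat_idx))))
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry,
            random_state=_target_seed(seed, str(target)), n_jobs=1)
        rf.fit(X, y)
        imp = rf.feature_importances_
        s = imp.sum()
        if s > 0:
            imp = imp / s
        for j, v in zip(feat_idx, imp):
            rows.append((cluster, regs[j], target, float(v)))
    return pd.DataFrame(rows, columns=["cluster", "regulator", "target", "importance"])


def _retain(edges: pd.DataFrame, top_e_per_target, importance_threshold) -> pd.DataFrame:
    if importance_threshold is not None:
        return edges[edges["importance"] >= importance_threshold]
    kept = []
    for (_, _), grp in edges.groupby(["cluster", "target"], sort=False):
        grp = grp.sort_values(["importance", "regulator"],
                              ascending=[False, True], kind="mergesort")
        kept.append(grp.head(top_e_per_target))
    return pd.concat(kept) if kept else edges.iloc[:0]


def rank_hubs(edges: pd.DataFrame, top_e_per_target: int = 5,
              importance_threshold: float | None = None,
              per_cluster: bool = False) -> pd.DataFrame:
    """Rank regulators by connectivity degree over retained edges.

    Retention keeps each target's top-E regulators by importance (default
    E=5), or every edge above `importance_threshold` when given. Degree is
    the count of retained out-edges pooled across clusters; ties are
    broken by total retained importance, then by regulator id.

    Returns a DataFrame (regulator, degree, total_importance, rank);
    with ``per_cluster=True`` a (cluster, regulator, degree) table
    instead.
    """
    if edges.empty:
        cols = (["cluster", "regulator", "degree"] if per_cluster
                else ["regulator", "degree", "total_importance", "rank"])
        return pd.DataFrame(columns=cols)
    retained = _retain(edges, top_e_per_target, importance_threshold)
    if per_cluster:
        out = (retained.groupby(["cluster", "regulator"]).size()
               .rename("degree").reset_index())
        return out.sort_values(["cluster", "degree"], ascending=[True, False],
                               kind="mergesort").reset_index(drop=True)
    agg = retained.groupby("regulator").agg(
        degree=("target", "size"), total_importance=("importance", "sum"))
    agg = agg.sort_values(["degree", "total_importance", "regulator"],
                          ascending=[False, False, True], kind="mergesort")
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg.reset_index()
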