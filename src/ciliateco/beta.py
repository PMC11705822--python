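"""Beta diversity: Bray-Curtis dissimilarity, NMDS, ANOSIM, Mantel tests
and between-group dissimilarity summaries.

Permutation tests use seeded generators and the add-one rule
``p = (exceedances + 1) / (n_perm + 1)`` so p can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from sklearn.manifold import MDS


@dataclass
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = ""

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic, "p_value": self.p_value,
            "n_permutations": self.n_permutations, "seed": self.seed,
            "method": self.method,
        }


_TRANSFORMS = {
    "none": lambda x: x,
    "sqrt": np.sqrt,
    "log1p": np.log1p,
}


def bray_curtis(table, transform: str = "none") -> DistanceMatrix:
    """Bray-Curtis dissimilarity: BC(x, y) = 1 - 2 sum(min) / sum(x + y)."""
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    values = _TRANSFORMS[transform](table.values)
    totals = values.sum(axis=1)
    if (totals == 0).any():
        bad = list(table.samples[totals == 0])
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {bad}")
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in table.samples])


def env_distance(env, variable: str, standardize: bool = True) -> DistanceMatrix:
    """1-D Euclidean distances of a (z-standardized) environmental variable."""
    if variable not in env.data.columns:
        raise KeyError(f"no such environmental variable: {variable}")
    x = env.data[variable].to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = list(env.samples[np.isnan(x)])
        raise ValueError(f"missing values for {variable}: {bad}")
    if standardize:
        sd = x.std(ddof=1)
        if sd > 0:
            x = (x - x.mean()) / sd
        else:
            x = np.zeros_like(x)
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(d, ids=[str(s) for s in env.samples])


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, float]:
    """Non-metric multidimensional scaling (SMACOF with isotonic regression).

    Best of ``n_starts`` random starts; returns coordinates and Kruskal
    stress-1 in [0, 1].
    """
    n = dm.shape[0]
    if k >= n:
        raise ValueError("embedding dimension must be below the sample count")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_starts,
        max_iter=max_iter,
        init="random",
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
    )
    coords = model.fit_transform(dm.data)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=list(dm.ids), columns=cols), float(model.stress_)


def _anosim_r(ranks_condensed: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    rb = ranks_condensed[~within_mask].mean()
    rw = ranks_condensed[within_mask].mean()
    return (rb - rw) / (n * (n - 1) / 4)


def anosim(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermTestResult:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks over all pairwise distances with average-rank ties; p by
    permutation of group labels.
    """
    labels = np.asarray(pd.Series(grouping).reindex(list(dm.ids))
                        if isinstance(grouping, pd.Series) else grouping)
    if len(labels) != dm.shape[0]:
        raise ValueError("grouping length does not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = list(uniq[counts < 2])
        raise ValueError(f"groups of size 1 have undefined within ranks: {small}")
    n = dm.shape[0]
    condensed = squareform(dm.data, checks=False)
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)

    codes = pd.factorize(labels)[0]
    within = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranks, within, n)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        within_p = perm[iu] == perm[ju]
        if _anosim_r(ranks, within_p, n) >= r_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermTestResult(float(r_obs), float(p), n_perm, seed, "anosim")


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermTestResult:
    """Mantel test: correlation of two distance matrices' upper triangles,
    one-sided p (positive association) by joint row/column permutation of
    the second matrix."""
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    v1 = d1.data[iu]

    def corr(a, b):
        if method == "spearman":
            a, b = rankdata(a), rankdata(b)
        a = a - a.mean()
        b = b - b.mean()
        den = np.sqrt((a * a).sum() * (b * b).sum())
        if den == 0:
            raise ValueError("zero variance in a distance triangle vector")
        return float((a * b).sum() / den)

    r_obs = corr(v1, d2.data[iu])
    rng = np.random.default_rng(seed)
    exceed = 0
    m2 = d2.data
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(v1, m2[np.ix_(perm, perm)][iu]) >= r_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermTestResult(r_obs, float(p), n_perm, seed, f"mantel-{method}")


def group_dissimilarity(
    dm: DistanceMatrix,
    grouping,
    n_boot: int = 999,
    seed: int | None = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Mean between-group dissimilarity for every group pair, with a seeded
    bootstrap CI over the between-group entries."""
    labels = pd.Series(grouping).reindex(list(dm.ids))
    rng = np.random.default_rng(seed)
    rows = []
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    for a, b in combinations(pd.unique(labels.dropna()), 2):
        ia = np.flatnonzero((labels == a).to_numpy())
        ib = np.flatnonzero((labels == b).to_numpy())
        entries = dm.data[np.ix_(ia, ib)].ravel()
        boots = np.array([
            entries[rng.integers(0, len(entries), len(entries))].mean()
            for _ in range(n_boot)
        ])
        rows.append({
            "group_a": a, "group_b": b,
            "mean_dissimilarity": float(entries.mean()),
            "ci_low": float(np.quantile(boots, lo_q)),
            "ci_high": float(np.quantile(boots, hi_q)),
            "n_pairs": len(entries),
        })
    return pd.DataFrame(rows)
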