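"""Constrained ordination and variation partitioning.

Redundancy analysis (RDA) regresses a (typically Hellinger-transformed)
community matrix on predictors under a linear response model; canonical
correspondence analysis (CCA) does the same under the chi-square/unimodal
model with row-total weights.  Both report the fraction of total variance
(inertia) captured by the constrained projection, and an adjusted version:
Ezekiel's formula for RDA, a permutation correction for CCA (Ezekiel is
biased there).

Spatial predictors are PCNM eigenvectors: principal coordinates of a
great-circle distance matrix truncated at the longest minimum-spanning-tree
edge, the standard multiscale spatial basis.

Forward selection is greedy with three guards: a permutation test on each
entering candidate, a cap at the full model's adjusted R-squared, and a
global permutation pre-test of the full model.  Variation partitioning
solves the inclusion-exclusion system over 2 or 3 predictor sets on the
adjusted-R-squared scale; negative fractions are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .core import AbundanceTable, EnvFrame, SampleFrame

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# transforms and response preparation

def hellinger(table: AbundanceTable) -> pd.DataFrame:
    """Square root of within-sample proportions."""
    values = table.values
    totals = values.sum(axis=1)
    if (totals == 0).any():
        bad = list(table.samples[totals == 0])
        raise ValueError(f"Hellinger transform undefined for all-zero samples: {bad}")
    return pd.DataFrame(np.sqrt(values / totals[:, None]),
                        index=table.samples, columns=table.taxa)


def _as_matrix(Y) -> pd.DataFrame:
    if isinstance(Y, AbundanceTable):
        return Y.data
    return pd.DataFrame(Y)


def _prepare_response(Y, method: str, transform: str | None):
    """Return (M, w): whitened response matrix and row weights.

    For RDA, M is the column-centered (optionally transformed) matrix and
    weights are uniform.  For CCA, M is the chi-square standardized
    residual matrix (which already embeds the sqrt row weights) and w holds
    the row masses used to weight the predictors.
    """
    Ydf = _as_matrix(Y)
    if method == "rda":
        if transform == "hellinger":
            if not isinstance(Y, AbundanceTable):
                Y = AbundanceTable(Ydf)
            Ydf = hellinger(Y)
        elif transform in ("sqrt", "log1p"):
            Ydf = Ydf.apply(np.sqrt if transform == "sqrt" else np.log1p)
        elif transform not in (None, "none"):
            raise ValueError(f"unknown transform {transform!r}")
        M = Ydf.to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        w = np.full(M.shape[0], 1.0 / M.shape[0])
        return M, w
    if method == "cca":
        A = Ydf.to_numpy(dtype=float)
        if (A < 0).any():
            raise ValueError("CCA requires non-negative abundances")
        rs, cs = A.sum(axis=1), A.sum(axis=0)
        if (rs == 0).any():
            raise ValueError(
                f"zero row sums: {list(Ydf.index[rs == 0])}")
        if (cs == 0).any():
            raise ValueError(
                f"zero column sums: {list(Ydf.columns[cs == 0])}")
        total = A.sum()
        P = A / total
        r, c = rs / total, cs / total
        M = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        return M, r
    raise ValueError(f"unknown method {method!r}")


def _weighted_design(X: pd.DataFrame, w: np.ndarray) -> np.ndarray:
    """Center columns by the weighted mean and scale rows by sqrt(w)."""
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    mean = w @ Xv
    return np.sqrt(w)[:, None] * (Xv - mean)


def _orthobasis(Xw: np.ndarray, tol: float = 1e-9):
    """Orthonormal basis of the column span; returns (Q, kept_idx)."""
    if Xw.size == 0 or Xw.shape[1] == 0:
        return np.empty((Xw.shape[0], 0)), []
    Qm, R, piv = qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.empty((Xw.shape[0], 0)), []
    rank = int((diag > tol * diag[0]).sum())
    kept = sorted(piv[:rank])
    Qm, _ = np.linalg.qr(Xw[:, kept])
    return Qm, kept


def _r2(Q: np.ndarray, M: np.ndarray, ss_total: float) -> float:
    if Q.shape[1] == 0:
        return 0.0
    proj = Q.T @ M
    return float((proj * proj).sum() / ss_total)


def ezekiel_adjusted(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _perm_mean_r2(Q: np.ndarray, M: np.ndarray, ss_total: float,
                  n_perm: int, rng) -> float:
    """Mean R-squared under row permutation of the response."""
    n = M.shape[0]
    acc = 0.0
    for _ in range(n_perm):
        acc += _r2(Q, M[rng.permutation(n)], ss_total)
    return acc / n_perm


# ---------------------------------------------------------------------------
# ordination fits

@dataclass
class OrdinationFit:
    method: str
    constrained_r2: float
    adjusted_r2: float
    eigenvalues: np.ndarray
    total_inertia: float
    rank: int
    n_samples: int
    site_scores: pd.DataFrame
    coefficients: pd.DataFrame | None = None
    dropped_columns: list = field(default_factory=list)


def _fit(Y, X, method: str, transform: str | None,
         n_perm: int, seed) -> OrdinationFit:
    M, w = _prepare_response(Y, method, transform)
    Ydf = _as_matrix(Y)
    n = M.shape[0]
    ss_total = float((M * M).sum())
    if ss_total == 0:
        raise ValueError("response matrix has zero total variance")

    if X is None or (hasattr(X, "shape") and np.size(X) == 0) or (
            isinstance(X, pd.DataFrame) and X.shape[1] == 0):
        # unconstrained: PCA of the centered matrix / correspondence analysis
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        eig = s ** 2 / (n - 1) if method == "rda" else s ** 2
        keep = eig > 1e-12 * max(eig.max(), 1e-300)
        scores = pd.DataFrame(
            U[:, keep] * s[keep],
            index=Ydf.index,
            columns=[f"Axis{i + 1}" for i in range(int(keep.sum()))],
        )
        return OrdinationFit(method, 0.0, 0.0, eig[keep], ss_total, 0, n, scores)

    Xdf = pd.DataFrame(X)
    if len(Xdf) != n:
        raise ValueError("predictors and response have different sample counts")
    Xw = _weighted_design(Xdf, w)
    Q, kept = _orthobasis(Xw)
    dropped = [c for i, c in enumerate(Xdf.columns) if i not in kept]
    m = Q.shape[1]
    if n <= m + 1:
        raise ValueError("too few samples for the number of predictors")
    r2 = _r2(Q, M, ss_total)
    if method == "rda":
        adj = ezekiel_adjusted(r2, n, m)
    else:
        rng = np.random.default_rng(seed)
        mean_null = _perm_mean_r2(Q, M, ss_total, n_perm, rng)
        adj = 1.0 - (1.0 - r2) / (1.0 - mean_null) if mean_null < 1 else np.nan

    fitted = Q @ (Q.T @ M)
    U, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = (s ** 2 / (n - 1)) if method == "rda" else s ** 2
    keep = eig > 1e-12 * max(eig.max(), 1e-300)
    scores = pd.DataFrame(
        U[:, keep] * s[keep], index=Ydf.index,
        columns=[f"Axis{i + 1}" for i in range(int(keep.sum()))])
    coef, *_ = np.linalg.lstsq(Xw[:, [Xdf.columns.get_loc(c) for c in Xdf.columns
                                      if c not in dropped]], M, rcond=None)
    kept_cols = [c for c in Xdf.columns if c not in dropped]
    coefficients = pd.DataFrame(coef, index=kept_cols, columns=Ydf.columns)
    return OrdinationFit(method, r2, adj, eig[keep], ss_total, m, n,
                         scores, coefficients, dropped)


def rda(Y, X=None, transform: str | None = None) -> OrdinationFit:
    """Redundancy analysis; with no predictors this is a PCA of Y."""
    return _fit(Y, X, "rda", transform, 0, None)


def cca(Y, X=None, n_perm: int = 999, seed: int | None = 0) -> OrdinationFit:
    """Canonical correspondence analysis; with no predictors this is CA.

    The adjusted R-squared uses the permutation correction
    ``1 - (1 - R2) / (1 - mean(R2_perm))``.
    """
    return _fit(Y, X, "cca", None, n_perm, seed)


# ---------------------------------------------------------------------------
# PCNM spatial eigenvectors

@dataclass
class SpatialEigenvectors:
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    truncation: float

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Great-circle distances (km) between all coordinate pairs."""
    lam, phi = np.radians(lon), np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _mst_max_edge(d: np.ndarray) -> float:
    """Longest edge of the minimum spanning tree (Prim's algorithm)."""
    n = d.shape[0]
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = d[0].copy()
    best[0] = np.inf
    longest = 0.0
    for _ in range(n - 1):
        j = int(np.argmin(np.where(in_tree, np.inf, best)))
        longest = max(longest, best[j])
        in_tree[j] = True
        best = np.minimum(best, d[j])
    return longest


def pcnm(coords, eig_tol: float = 1e-8) -> SpatialEigenvectors:
    """Principal coordinates of neighbour matrices on lon/lat coordinates.

    Distances are great-circle; the truncation threshold is the longest
    minimum-spanning-tree edge among distinct sites; distances above it are
    replaced by four times the threshold before double-centered principal
    coordinate analysis.  Only positive-eigenvalue axes are returned, unit
    norm, in decreasing eigenvalue order.
    """
    cdf = pd.DataFrame(coords)
    if {"longitude", "latitude"}.issubset(cdf.columns):
        lon = cdf["longitude"].to_numpy(float)
        lat = cdf["latitude"].to_numpy(float)
    else:
        lon = cdf.iloc[:, 0].to_numpy(float)
        lat = cdf.iloc[:, 1].to_numpy(float)
    index = cdf.index

    sites = np.column_stack([lon, lat])
    distinct = np.unique(np.round(sites, 9), axis=0)
    if len(distinct) < 3:
        if len(distinct) == 1:
            return SpatialEigenvectors(
                pd.DataFrame(index=index), np.array([]), 0.0)
        raise ValueError("PCNM needs at least 3 distinct sites")

    d = haversine_matrix(lon, lat)
    d_sites = haversine_matrix(distinct[:, 0], distinct[:, 1])
    t = _mst_max_edge(d_sites)
    dtrunc = np.where(d > t, 4.0 * t, d)
    np.fill_diagonal(dtrunc, 0.0)

    a = -0.5 * dtrunc ** 2
    a = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigval, eigvec = np.linalg.eigh(a)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > eig_tol * max(eigval.max(), 1e-300)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    # deterministic sign: largest-magnitude element positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = pd.DataFrame(eigvec, index=index,
                          columns=[f"PCNM{i + 1}" for i in range(eigvec.shape[1])])
    return SpatialEigenvectors(scores, eigval, float(t))


# ---------------------------------------------------------------------------
# forward selection

@dataclass
class ForwardSelectResult:
    selected: list
    trace: pd.DataFrame
    full_adjusted_r2: float
    global_p: float | None


def forward_select(
    Y,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "rda",
    transform: str | None = None,
    global_test: bool = True,
    r2_cap: bool = True,
) -> ForwardSelectResult:
    """Greedy permutation-tested predictor selection.

    At each step the candidate adding the most explained variance is
    tested by permuting its residuals (given the already-selected set);
    it enters iff its marginal p < ``alpha`` and — when ``r2_cap`` — the
    cumulative adjusted R-squared stays at or below the full model's.
    When ``global_test`` is on, selection is attempted only if the full
    candidate model itself passes a permutation test at ``alpha``; this
    keeps the family-wise error of selecting anything from pure noise
    near ``alpha``.  An empty selection is a valid outcome.
    """
    if candidates.shape[1] == 0:
        raise ValueError("candidate set must be non-empty")
    M, w = _prepare_response(Y, method, transform)
    n = M.shape[0]
    ss_total = float((M * M).sum())
    Xw_all = _weighted_design(candidates, w)
    rng = np.random.default_rng(seed)

    Q_full, _ = _orthobasis(Xw_all)
    r2_full = _r2(Q_full, M, ss_total)
    if method == "rda":
        adj_full = ezekiel_adjusted(r2_full, n, Q_full.shape[1])
    else:
        adj_full = 1.0 - (1.0 - r2_full) / (
            1.0 - _perm_mean_r2(Q_full, M, ss_total, max(n_perm, 99), rng))

    global_p = None
    if global_test:
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _r2(Q_full, M[rng.permutation(n)], ss_total)
        global_p = float(((null >= r2_full).sum() + 1) / (n_perm + 1))
        if global_p >= alpha:
            trace = pd.DataFrame(
                [{"step": 0, "candidate": "<global test>", "added_r2": r2_full,
                  "p_value": global_p, "cumulative_adj_r2": 0.0,
                  "entered": False, "reason": "global model not significant"}])
            return ForwardSelectResult([], trace, adj_full, global_p)

    names = list(candidates.columns)
    remaining = list(range(len(names)))
    selected: list[int] = []
    Qsel = np.empty((n, 0))
    r2_sel = 0.0
    trace_rows = []
    step = 0
    while remaining:
        step += 1
        Mres = M - Qsel @ (Qsel.T @ M)
        ss_res = float((Mres * Mres).sum())
        if ss_res <= 1e-12 * ss_total:
            break
        Xres = Xw_all[:, remaining] - Qsel @ (Qsel.T @ Xw_all[:, remaining])
        norms2 = (Xres * Xres).sum(axis=0)
        num = (Xres.T @ Mres)
        added = np.where(norms2 > 1e-12,
                         (num * num).sum(axis=1) / np.maximum(norms2, 1e-300), 0.0)
        added_r2 = added / ss_total
        k = int(np.argmax(added_r2))
        if added_r2[k] <= 0:
            break
        idx = remaining[k]
        x = Xres[:, k]
        # statistic: SS explained by the candidate's residual direction;
        # permuting its entries preserves the norm, so the scale cancels
        stat_obs = added[k]
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        Xp = x[perm_idx]                         # n_perm x n
        stat_perm = ((Xp @ Mres) ** 2).sum(axis=1) / norms2[k]
        p = float(((stat_perm >= stat_obs - 1e-15).sum() + 1) / (n_perm + 1))

        cum_r2 = r2_sel + added_r2[k]
        if method == "rda":
            cum_adj = ezekiel_adjusted(cum_r2, n, len(selected) + 1)
        else:
            Qtry, _ = _orthobasis(Xw_all[:, selected + [idx]])
            cum_adj = 1.0 - (1.0 - cum_r2) / (
                1.0 - _perm_mean_r2(Qtry, M, ss_total, max(n_perm, 99), rng))

        # the adjusted-R2 cap guards against accumulation in later steps;
        # the first entry is already protected by the global pre-test, and a
        # lone strong driver legitimately beats the noise-deflated full model
        cap_active = r2_cap and len(selected) >= 1
        enters = p < alpha and (not cap_active or cum_adj <= adj_full + 1e-12)
        reason = "" if enters else (
            f"p {p:.4f} >= alpha" if p >= alpha
            else "adjusted R2 cap reached")
        trace_rows.append({
            "step": step, "candidate": names[idx], "added_r2": float(added_r2[k]),
            "p_value": p, "cumulative_adj_r2": float(cum_adj),
            "entered": enters, "reason": reason,
        })
        if not enters:
            break
        selected.append(idx)
        remaining.remove(idx)
        Qsel, _ = _orthobasis(Xw_all[:, selected])
        r2_sel = _r2(Qsel, M, ss_total)

    trace = pd.DataFrame(trace_rows, columns=[
        "step", "candidate", "added_r2", "p_value",
        "cumulative_adj_r2", "entered", "reason"])
    return ForwardSelectResult([names[i] for i in selected], trace,
                               float(adj_full), global_p)


# ---------------------------------------------------------------------------
# variation partitioning

@dataclass
class VarpartResult:
    labels: list
    fractions: dict           # unique/shared adjusted-R2 fractions
    union_adjusted_r2: dict   # adjusted R2 of every testable union
    residual: float
    method: str

    def as_series(self) -> pd.Series:
        out = dict(self.fractions)
        out["residual"] = self.residual
        return pd.Series(out)


def _union_adj(M, ss_total, w, Xs: list[pd.DataFrame], method, n_perm, rng) -> float:
    X = pd.concat(Xs, axis=1)
    Xw = _weighted_design(X, w)
    Q, _ = _orthobasis(Xw)
    n, m = M.shape[0], Q.shape[1]
    if m >= n - 1:
        raise ValueError("combined predictor rank too high for the sample count")
    r2 = _r2(Q, M, ss_total)
    if method == "rda":
        return ezekiel_adjusted(r2, n, m)
    mean_null = _perm_mean_r2(Q, M, ss_total, n_perm, rng)
    return 1.0 - (1.0 - r2) / (1.0 - mean_null)


def varpart(
    Y,
    sets: dict[str, pd.DataFrame],
    method: str = "rda",
    transform: str | None = "hellinger",
    n_perm: int = 999,
    seed: int | None = 0,
) -> VarpartResult:
    """Adjusted-R-squared variation partitioning over 2 or 3 predictor sets.

    Fits every union of predictor sets, converts each to adjusted
    R-squared, and solves the inclusion-exclusion system for unique and
    shared fractions.  Negative fractions are reported as-is (standard
    semantics: shared fractions are not variances).
    """
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValueError("varpart requires 2 or 3 predictor sets")
    for name, X in sets.items():
        if X.shape[1] == 0:
            raise ValueError(f"predictor set {name!r} is empty")
    M, w = _prepare_response(Y, method, transform)
    ss_total = float((M * M).sum())
    rng = np.random.default_rng(seed)

    adj = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            adj[combo] = _union_adj(M, ss_total, w, [sets[c] for c in combo],
                                    method, n_perm, rng)

    fractions: dict[str, float] = {}
    if len(labels) == 2:
        a_, b_ = labels
        sab = adj[(a_, b_)]
        fractions[f"unique[{a_}]"] = sab - adj[(b_,)]
        fractions[f"unique[{b_}]"] = sab - adj[(a_,)]
        fractions[f"shared[{a_}&{b_}]"] = adj[(a_,)] + adj[(b_,)] - sab
        residual = 1.0 - sab
    else:
        a_, b_, c_ = labels
        SA, SB, SC = adj[(a_,)], adj[(b_,)], adj[(c_,)]
        SAB, SAC, SBC = adj[(a_, b_)], adj[(a_, c_)], adj[(b_, c_)]
        SABC = adj[(a_, b_, c_)]
        g = SA + SB + SC - SAB - SAC - SBC + SABC
        fractions[f"unique[{a_}]"] = SABC - SBC
        fractions[f"unique[{b_}]"] = SABC - SAC
        fractions[f"unique[{c_}]"] = SABC - SAB
        fractions[f"shared[{a_}&{b_}]"] = SA + SB - SAB - g
        fractions[f"shared[{b_}&{c_}]"] = SB + SC - SBC - g
        fractions[f"shared[{a_}&{c_}]"] = SA + SC - SAC - g
        fractions[f"shared[{a_}&{b_}&{c_}]"] = g
        residual = 1.0 - SABC

    unions = {"+".join(k): v for k, v in adj.items()}
    return VarpartResult(labels, fractions, unions, float(residual), method)


# ---------------------------------------------------------------------------
# predictor assembly

def build_predictor_sets(
    frame: SampleFrame,
    env: EnvFrame | None = None,
    pcnm_axes: SpatialEigenvectors | pd.DataFrame | None = None,
    depth_log: bool = False,
) -> dict[str, pd.DataFrame]:
    """Named predictor sets: season / vertical / horizontal and the
    physical / chemical / food environment groups."""
    idx = frame.samples
    sets: dict[str, pd.DataFrame] = {}
    season = (frame.data["season"] == "summer").astype(float)
    sets["season"] = pd.DataFrame({"season_summer": season}, index=idx)
    vert = {"depth": frame.data["sample_depth"].astype(float)}
    if depth_log:
        vert["log_depth"] = np.log1p(frame.data["sample_depth"].astype(float))
    sets["vertical"] = pd.DataFrame(vert, index=idx)
    if pcnm_axes is not None:
        scores = pcnm_axes.scores if isinstance(pcnm_axes, SpatialEigenvectors) else pcnm_axes
        sets["horizontal"] = scores.reindex(idx)
    if env is not None:
        for g in ("physical", "chemical", "food"):
            sets[g] = env.group(g).reindex(idx)
    return sets
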