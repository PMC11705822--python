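"""Alpha diversity: per-sample metrics, group comparisons, shared species,
and diversity-environment correlation screens."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceTable, EnvFrame


def alpha_metrics(table: AbundanceTable, base: str = "e") -> pd.DataFrame:
    """Species richness, Shannon entropy and total abundance per sample.

    Shannon is computed on within-sample proportions in natural log by
    default (``base='2'`` switches to bits).  All-zero samples get NaN
    entropy — undefined, not zero.
    """
    values = table.values
    totals = values.sum(axis=1)
    richness = (values > 0).sum(axis=1)
    shannon = np.full(len(totals), np.nan)
    log = np.log2 if base == "2" else np.log
    for i, row in enumerate(values):
        if totals[i] > 0:
            p = row[row > 0] / totals[i]
            shannon[i] = float(-(p * log(p)).sum())
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "total_abundance": totals},
        index=table.samples,
    )


def tukey_hsd(values: pd.Series, grouping: pd.Series) -> pd.DataFrame:
    """All-pairs Tukey HSD on a per-sample metric.

    Adjusted p-values come from the studentized range distribution with
    ``N - k`` degrees of freedom.  Returns a tidy table of group pairs with
    mean differences and adjusted p.
    """
    groups = grouping.reindex(values.index)
    if groups.isna().any():
        raise ValueError("grouping does not cover all samples")
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[groups == g].to_numpy(dtype=float) for g in levels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 samples")
    n_total = sum(len(a) for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within <= 0:
        raise ValueError("zero within-group variance: Tukey HSD is degenerate")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(levels)), 2):
        rows.append({
            "group_a": levels[i],
            "group_b": levels[j],
            "mean_difference": arrays[i].mean() - arrays[j].mean(),
            "p_adj": float(res.pvalue[i, j]),
        })
    out = pd.DataFrame(rows)
    out.attrs["df_within"] = n_total - len(levels)
    return out


def shared_species(table: AbundanceTable, grouping: pd.Series) -> dict:
    """Per-group species counts and all intersection sizes (Venn numbers).

    A species counts toward a group iff it is present (abundance > 0) in at
    least one sample of the group.
    """
    groups = grouping.reindex(table.samples)
    if groups.isna().any():
        raise ValueError("grouping does not cover all samples")
    present = table.data > 0
    sets = {
        g: set(table.taxa[present[groups == g].any(axis=0)])
        for g in pd.unique(groups)
    }
    levels = list(sets)
    result = {
        "per_group": {g: len(s) for g, s in sets.items()},
        "pairwise_shared": {
            (a, b): len(sets[a] & sets[b]) for a, b in combinations(levels, 2)
        },
        "all_shared": len(set.intersection(*sets.values())) if sets else 0,
        "unique": {
            g: len(sets[g] - set.union(*(sets[h] for h in levels if h != g)))
            if len(levels) > 1 else len(sets[g])
            for g in levels
        },
    }
    return result


def alpha_env_correlation(
    alpha: pd.DataFrame,
    env: EnvFrame,
    method: str = "spearman",
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Correlate each alpha metric with each environmental variable.

    Spearman rank correlation (tie-corrected) by default, Pearson
    selectable.  Returns a tidy frame with the coefficient, two-sided p and
    a significance mask (cells with p > ``alpha_level`` are masked, the
    convention of the diversity-environment heatmap).  Constant variables
    yield a masked NaN with a reason.
    """
    env_data = env.data.reindex(alpha.index)
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for metric in alpha.columns:
        x = alpha[metric]
        for var in env_data.columns:
            y = env_data[var]
            ok = x.notna() & y.notna()
            reason = ""
            if ok.sum() < 3:
                rho, p = np.nan, np.nan
                reason = "fewer than 3 paired observations"
            elif y[ok].nunique() == 1 or x[ok].nunique() == 1:
                rho, p = np.nan, np.nan
                reason = "constant input"
            else:
                rho, p = corr(x[ok], y[ok])
            rows.append({
                "metric": metric, "variable": var,
                "coefficient": float(rho) if rho == rho else np.nan,
                "p_value": float(p) if p == p else np.nan,
                "significant": bool(p == p and p < alpha_level),
                "masked_reason": reason,
            })
    return pd.DataFrame(rows)
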