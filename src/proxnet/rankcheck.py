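"""Rank-order consistency and replicate-comparison checks.

A model-free companion to the variance-component repeatability: if
individuals differ consistently, their *ranking* by a metric should be
stable across the six measurement occasions (3 densities x 2
replicates).  Kendall's coefficient of concordance W (tie-corrected) and
the mean pairwise Spearman correlation between occasions quantify this;
Wilcoxon rank-sum tests compare the two replicates of each density.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rank_table",
    "rank_order_repeatability",
    "compare_replicates",
    "kendalls_w",
]


def rank_table(obs: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Individuals x occasions matrix of within-occasion ranks (ties
    mid-ranked), occasions ordered by (density, replicate)."""
    sub = obs[obs["metric"] == metric]
    wide = sub.pivot_table(index="individual", columns=["density", "replicate"],
                           values="value")
    ranks = wide.apply(lambda col: stats.rankdata(col, method="average"), axis=0)
    return pd.DataFrame(ranks, index=wide.index, columns=wide.columns)


def kendalls_w(ranks: np.ndarray | pd.DataFrame) -> float:
    """Tie-corrected Kendall coefficient of concordance.

    *ranks* is individuals x occasions, each column a (tie-adjusted)
    ranking of the n individuals by one occasion.

        W = 12 S / (m^2 (n^3 - n) - m T),  S = sum_i (R_i - R_bar)^2,
        T = sum over occasions of sum over tie groups of (t^3 - t).

    Returns nan when every occasion is fully tied (denominator zero).
    """
    R = np.asarray(ranks, dtype=float)
    n, m = R.shape
    if m < 2 or n < 3:
        raise ValueError("need >= 2 occasions and >= 3 individuals")
    totals = R.sum(axis=1)
    S = np.sum((totals - totals.mean()) ** 2)
    T = 0.0
    for j in range(m):
        _, counts = np.unique(R[:, j], return_counts=True)
        T += float(np.sum(counts.astype(float) ** 3 - counts))
    denom = m * m * (n ** 3 - n) - m * T
    if denom <= 0:
        return float("nan")
    return float(12.0 * S / denom)


def rank_order_repeatability(ranks: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Kendall's W across occasions plus the mean of all pairwise Spearman
    correlations between occasions.  Occasion pairs whose Spearman
    correlation is undefined (an all-tied occasion) are skipped in the
    mean; a fully degenerate table yields (nan, nan)."""
    R = np.asarray(ranks, dtype=float)
    w = kendalls_w(R)
    m = R.shape[1]
    rhos = []
    for a, b in itertools.combinations(range(m), 2):
        if np.ptp(R[:, a]) == 0 or np.ptp(R[:, b]) == 0:
            continue
        rhos.append(stats.spearmanr(R[:, a], R[:, b]).statistic)
    mean_rho = float(np.mean(rhos)) if rhos else float("nan")
    return w, mean_rho


def compare_replicates(obs: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of replicate 1 vs replicate 2 for
    each metric x density.

    Uses the exact null distribution when both groups have n <= 12 and no
    cross-group ties, otherwise the normal approximation with continuity
    correction.  Identical replicate samples give p = 1 under the exact
    test."""
    rows = []
    for (metric, density), grp in obs.groupby(["metric", "density"]):
        x = grp.loc[grp["replicate"] == 1, "value"].to_numpy(dtype=float)
        y = grp.loc[grp["replicate"] == 2, "value"].to_numpy(dtype=float)
        if x.size == 0 or y.size == 0:
            continue
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (max(x.size, y.size) <= 12 and not has_ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                 use_continuity=True)
        rows.append({"metric": metric, "density": float(density),
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue), "method": method,
                     "n1": x.size, "n2": y.size})
    return pd.DataFrame(rows)
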