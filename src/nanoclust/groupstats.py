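"""Nonparametric group comparisons: Mann-Whitney, Kruskal-Wallis and
Friedman omnibus tests with Bonferroni-Dunn pairwise post-tests.

The omnibus statistics come from :mod:`scipy.stats`; the Dunn post-hoc
z-scores (rank-sum comparisons with tie correction, Bonferroni-adjusted
over all pairs) are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "kruskal_dunn",
    "friedman_dunn",
]


@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic, "pvalue": self.pvalue}
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def mann_whitney(a, b, alternative: str = "two-sided") -> GroupComparison:
    """Mann-Whitney U rank test.

    Exact null distribution when both samples have n <= 8 and there are
    no ties; tie-corrected normal approximation otherwise.  Two groups
    with all values identical give p = 1 rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate((a, b))
    if np.all(pooled == pooled[0]):
        return GroupComparison("mann-whitney", statistic=len(a) * len(b) / 2.0, pvalue=1.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison("mann-whitney", statistic=float(res.statistic), pvalue=float(res.pvalue))


def _dunn_posthoc_kw(groups) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction."""
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "z": z,
                "pvalue": p,
                "pvalue_adjusted": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)


def kruskal_dunn(groups) -> GroupComparison:
    """Kruskal-Wallis H test with Bonferroni-Dunn pairwise post-tests.

    Requires >= 3 groups; with two groups use :func:`mann_whitney`.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; use mann_whitney for 2")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        posthoc = _dunn_posthoc_kw(groups)
        return GroupComparison("kruskal-wallis", 0.0, 1.0, posthoc)
    h, p = stats.kruskal(*groups)
    return GroupComparison("kruskal-wallis", float(h), float(p), _dunn_posthoc_kw(groups))


def friedman_dunn(matrix) -> GroupComparison:
    """Row-matched Friedman test with Dunn's pairwise post-tests.

    ``matrix`` is subjects x conditions, complete (no missing cells).
    Post-hoc z for conditions i, j uses the within-row rank sums:
    z = (R_i - R_j) / sqrt(n k (k + 1) / 6), Bonferroni-adjusted.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x conditions)")
    n, k = x.shape
    if k < 3:
        raise ValueError("Friedman test requires >= 3 conditions")
    if np.isnan(x).any():
        raise ValueError("matched-values Friedman test requires a complete matrix")

    row_ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rank_sums = row_ranks.sum(axis=0)
    if np.allclose(x, x[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*(x[:, j] for j in range(k)))
    m = k * (k - 1) // 2
    se = np.sqrt(n * k * (k + 1) / 6.0)
    rows = []
    for i, j in combinations(range(k), 2):
        z = (rank_sums[i] - rank_sums[j]) / se
        pv = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "z": z,
                "pvalue": pv,
                "pvalue_adjusted": min(1.0, pv * m),
            }
        )
    return GroupComparison("friedman", float(stat), float(p), pd.DataFrame(rows))
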