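"""Nonparametric group comparisons and exact tests used in the analyses.

Two-group comparisons use Wilcoxon's rank-sum test (exact for small
samples), paired comparisons the signed-rank test, and multi-group
comparisons Kruskal-Wallis; per-animal above-chance claims use the exact
one-sided binomial tail.  Effect sizes are reported as the fraction of
total variance accounted for by the grouping factor.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as ss


def compare_groups(x, y=None, test: str = "ranksum", groups=None):
    """Nonparametric comparison; returns (statistic, p).

    test: "ranksum" (two independent groups, exact for small n),
    "signedrank" (paired), or "kruskal" (``groups`` = list of arrays).
    """
    if test == "ranksum":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size == 0 or y.size == 0:
            raise ValueError("empty group")
        method = "exact" if (len(x) <= 25 and len(y) <= 25
                             and _no_ties(x, y)) else "auto"
        res = ss.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "signedrank":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size == 0:
            raise ValueError("empty group")
        res = ss.wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal":
        data = groups if groups is not None else [x, y]
        if any(len(g) == 0 for g in data):
            raise ValueError("empty group")
        res = ss.kruskal(*data)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def _no_ties(x, y):
    z = np.concatenate([x, y])
    return len(np.unique(z)) == len(z)


def bonferroni(p_values, n_comparisons: int | None = None) -> np.ndarray:
    """Bonferroni-corrected p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(p * m, 1.0)


def binomial_above_chance(n_correct: int, n_total: int,
                          chance_p: float) -> float:
    """Exact one-sided binomial tail P(X >= n_correct | chance_p)."""
    if not 0 < chance_p < 1:
        raise ValueError("chance_p must be in (0, 1)")
    if n_correct > n_total or n_correct < 0:
        raise ValueError("invalid counts")
    return float(ss.binomtest(n_correct, n_total, chance_p,
                              alternative="greater").pvalue)


def variance_accounted(values, groups) -> float:
    """Effect size: between-group variance / total variance."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    grand = values.mean()
    ss_total = np.sum((values - grand) ** 2)
    if ss_total == 0:
        return 0.0
    ss_between = sum(
        np.sum(groups == g) * (values[groups == g].mean() - grand) ** 2
        for g in np.unique(groups))
    return float(ss_between / ss_total)
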