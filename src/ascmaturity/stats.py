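"""Comparison statistics used throughout the pipeline.

Two-group comparisons use the Mann-Whitney U test; three or more groups use
one-way ANOVA with Tukey's HSD correction or the Kruskal-Wallis test with
Bonferroni-corrected pairwise follow-ups. Correlations are Pearson, with the
qualitative labels poor (|r| < 0.3), fair (0.3-0.6), moderate (0.6-0.8) and
very strong (>= 0.8).

Thin, well-specified wrappers over scipy.stats; independent brute-force
oracles for these live in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "pearson",
    "classify_correlation",
    "mann_whitney",
    "anova_tukey",
    "kruskal_bonferroni",
    "median_ci",
]


@dataclass
class GroupComparison:
    """Result of a multi-group comparison."""

    test: str
    statistic: float
    p_value: float  # omnibus p
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_raw(opt), p_adjusted


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-distribution p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson needs two equal-length vectors of n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def classify_correlation(r: float) -> str:
    """Qualitative label for a correlation coefficient (on |r|)."""
    a = abs(r)
    if a > 1:
        raise ValueError(f"|r| = {a} exceeds 1")
    if a < 0.3:
        return "poor"
    if a < 0.6:
        return "fair"
    if a < 0.8:
        return "moderate"
    return "very strong"


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for group *x* vs *y*.

    Exact enumeration for small samples (both n <= 8, no ties), otherwise the
    tie-corrected normal approximation. Returns (U_x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _named_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"group{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def anova_tukey(groups, reference: str | None = None) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    With a *reference* group, only reference-vs-other pairs are reported
    (e.g., every immune stage against baseline). All-identical data yields
    F = 0, p = 1.
    """
    named = _named_groups(groups)
    names = list(named)
    if len(names) < 2 or any(len(v) < 2 for v in named.values()):
        raise ValueError("anova_tukey needs >= 2 groups of n >= 2")
    arrays = [named[n] for n in names]
    degenerate = np.ptp(np.concatenate(arrays)) == 0
    if degenerate:
        f_stat, p_omni = 0.0, 1.0
    else:
        f_stat, p_omni = sps.f_oneway(*arrays)
        if np.isnan(f_stat):
            f_stat, p_omni = 0.0, 1.0
    hsd = None if degenerate else sps.tukey_hsd(*arrays)
    rows = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            if reference is not None and reference not in (a, b):
                continue
            p_adj = 1.0 if degenerate else float(min(hsd.pvalue[i, j], 1.0))
            if np.isnan(p_adj):
                p_adj = 1.0
            rows.append({"group_a": a, "group_b": b, "p_adjusted": p_adj})
    return GroupComparison(test="anova_tukey", statistic=float(f_stat),
                           p_value=float(p_omni), pairwise=pd.DataFrame(rows))


def kruskal_bonferroni(groups, reference: str | None = None) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) with Bonferroni-adjusted pairwise
    Mann-Whitney follow-ups (raw p x number of comparisons, capped at 1)."""
    named = _named_groups(groups)
    names = list(named)
    if len(names) < 2:
        raise ValueError("kruskal_bonferroni needs >= 2 groups")
    arrays = [named[n] for n in names]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = sps.kruskal(*arrays)
    pairs = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            if reference is not None and reference not in (a, b):
                continue
            pairs.append((a, b))
    rows = []
    for a, b in pairs:
        _, p_raw = mann_whitney(named[a], named[b])
        rows.append({"group_a": a, "group_b": b, "p_raw": p_raw,
                     "p_adjusted": float(min(p_raw * len(pairs), 1.0))})
    return GroupComparison(test="kruskal_bonferroni", statistic=float(h_stat),
                           p_value=float(p_omni), pairwise=pd.DataFrame(rows))


def median_ci(values) -> tuple[float, float, float]:
    """Median with a notch-style 95% CI: median +/- 1.57*IQR/sqrt(n)."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    half = 1.57 * iqr / np.sqrt(len(v))
    return med, med - half, med + half
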