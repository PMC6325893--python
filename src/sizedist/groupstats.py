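"""Nonparametric group comparisons for size/fitness/deviance associations.

All three procedures are rank-based (hence invariant under strictly
monotone transformation of the pooled data) and two-sided:

* Wilcoxon rank-sum (Mann-Whitney) with midranks for ties — exact
  enumeration for small samples, otherwise a normal approximation with
  tie-corrected variance and optional continuity correction;
* Kruskal-Wallis H with tie correction and a chi-square reference;
* Nemenyi all-pairs post-hoc on mean-rank differences, referred to the
  studentized-range distribution.

p-values below 2.2e-16 are *printed* as "< 2.2e-16" (see
:func:`format_p`) while the raw value is retained in results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .histogram_io import ValidationError

P_FLOOR = 2.2e-16

EXACT_MAX_N = 10


@dataclass(frozen=True)
class GroupComparison:
    """Result of a rank-based group comparison."""

    test_name: str
    statistic: float
    p_value: float | np.ndarray  # pairwise matrix for nemenyi
    group_sizes: tuple[int, ...]
    continuity_correction: bool = False
    tie_correction: bool = True
    mode: str = ""


def format_p(p: float) -> str:
    """Report a p-value, flooring the printed form at the conventional
    2.2e-16 threshold."""
    return f"< {P_FLOOR:g}" if p < P_FLOOR else f"{p:g}"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """``sum(t^3 - t)`` over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    continuity: bool = True,
    mode: str = "auto",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test.

    ``mode="exact"`` enumerates every assignment of pooled midranks to the
    first group (feasible for n1, n2 <= 10; handles ties); ``"normal"``
    uses the tie-corrected normal approximation with an optional ±0.5
    continuity correction.  ``"auto"`` picks exact when both groups have at
    most 10 untied observations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())  # rank sum of the first group

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and not has_ties) else "normal"

    mu = n1 * (n1 + n2 + 1) / 2.0
    if mode == "exact":
        if n1 > 12 or n2 > 12:
            raise ValidationError("exact enumeration limited to group sizes <= 12")
        obs = abs(w - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
                count += 1
        p = count / total
    elif mode == "normal":
        n = n1 + n2
        var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            diff = abs(w - mu)
            if continuity:
                diff = max(diff - 0.5, 0.0)
            p = min(1.0, 2.0 * stats.norm.sf(diff / math.sqrt(var)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GroupComparison(
        test_name="wilcoxon_rank_sum",
        statistic=w,
        p_value=float(p),
        group_sizes=(n1, n2),
        continuity_correction=continuity and mode == "normal",
        tie_correction=True,
        mode=mode,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value.

    When every pooled value is identical the statistic is defined as 0 with
    p = 1 (there is no rank information at all).
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValidationError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    if n < 3:
        raise ValidationError("need at least three observations in total")
    ranks = _midranks(pooled)
    sizes = [a.size for a in arrays]
    h = 0.0
    start = 0
    for sz in sizes:
        rsum = ranks[start : start + sz].sum()
        h += rsum**2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:  # all values tied
        h, p = 0.0, 1.0
    else:
        h /= correction
        h = max(h, 0.0)
        p = float(stats.chi2.sf(h, len(arrays) - 1))
    return GroupComparison(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=p,
        group_sizes=tuple(sizes),
        tie_correction=True,
    )


def nemenyi_posthoc(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """All-pairs Nemenyi post-hoc test on pooled mean ranks.

    The pairwise statistic ``|Rbar_i - Rbar_j| / sqrt(C * N(N+1)/12 *
    (1/n_i + 1/n_j))`` (C = tie correction) is referred to the studentized
    range distribution with infinite degrees of freedom.  Returns a
    symmetric p-value matrix with unit diagonal.
    """
    arrays = [np.asarray(g, float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValidationError("need at least two groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = _midranks(pooled)
    sizes = np.array([a.size for a in arrays])
    means = []
    start = 0
    for sz in sizes:
        means.append(ranks[start : start + sz].mean())
        start += sz
    means = np.array(means)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    pmat = np.ones((k, k))
    qmax = 0.0
    if correction > 0:
        base_var = correction * n * (n + 1) / 12.0
        for i in range(k):
            for j in range(i + 1, k):
                se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
                q = abs(means[i] - means[j]) / se * math.sqrt(2.0)
                qmax = max(qmax, q)
                p = float(stats.studentized_range.sf(q, k, np.inf)) if q > 0 else 1.0
                pmat[i, j] = pmat[j, i] = min(1.0, p)
    return GroupComparison(
        test_name="nemenyi",
        statistic=qmax,
        p_value=pmat,
        group_sizes=tuple(int(s) for s in sizes),
        tie_correction=True,
    )
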