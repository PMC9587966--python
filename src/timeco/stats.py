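"""Group-comparison engine: two-sided Wilcoxon rank-sum and BH-FDR.

The rank-sum test uses exact enumeration of the permutation null (via a
counting recursion over rank subsets) when the pooled size is at most 12
and the data carry no ties; otherwise it falls back to the normal
approximation with tie-corrected variance and continuity correction.

A documented caveat: pairwise heterogeneity values within a patient share
samples and are therefore not independent.  Pooled-pair testing is
replicated as the field practises it; ``aggregate_per_patient`` offers a
patient-level median aggregation as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "GroupTestResult",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "compare_categories",
    "significance_stars",
]

EXACT_MAX_POOLED = 12


@dataclass
class GroupTestResult:
    metric: str
    category_a: str
    category_b: str
    n_a: int
    n_b: int
    statistic: float  # rank-sum W of the smaller group
    p_value: float
    p_adjusted: Optional[float] = None


def _ranksum_counts(ranks: Sequence[int], k: int) -> np.ndarray:
    """Number of k-subsets of ``ranks`` attaining each possible rank-sum.

    Index ``s`` of the returned vector counts subsets with sum ``s``.
    Dynamic programme over (subset size, sum); cost O(n * k * maxsum).
    """
    max_sum = sum(sorted(ranks)[-k:]) if k else 0
    table = np.zeros((k + 1, max_sum + 1), dtype=np.float64)
    table[0, 0] = 1.0
    for r in ranks:
        for size in range(k, 0, -1):
            table[size, r:] += table[size - 1, : max_sum + 1 - r]
    return table[k]


def _exact_two_sided_p(n_small: int, n_total: int, w_obs: int) -> float:
    """Exact two-sided p for the rank-sum of the smaller group.

    p = min(1, 2 * min(P(W <= w), P(W >= w))) under the null that every
    assignment of ranks 1..n_total to the two groups is equally likely.
    Valid only without ties.
    """
    counts = _ranksum_counts(range(1, n_total + 1), n_small)
    total = counts.sum()
    lo = counts[: w_obs + 1].sum() / total
    hi = counts[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank-sum (midranks) of the smaller
    group (group ``a`` on equal sizes).  Exact enumeration when the pooled
    sample is small and tie-free; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("NaN values are not permitted")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx, ry = ranks[: x.size], ranks[x.size :]
    if x.size <= y.size:
        w = float(rx.sum())
        n_small = x.size
    else:
        w = float(ry.sum())
        n_small = y.size
    n_total = x.size + y.size
    has_ties = np.unique(pooled).size < n_total
    if n_total <= EXACT_MAX_POOLED and not has_ties:
        p = _exact_two_sided_p(n_small, n_total, int(round(w)))
        return w, p
    # Normal approximation on the Mann-Whitney U statistic (equivalent to
    # the rank-sum), tie-corrected variance, continuity correction.
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return w, float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1) | np.isnan(p)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def significance_stars(p: float) -> str:
    """Figure-style annotation: * <=0.05, ** <=0.01, *** <=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_categories(
    pairs,
    metric: str,
    min_n: int = 2,
    aggregate_per_patient: bool = False,
) -> Tuple[List[GroupTestResult], List[str]]:
    """All category-vs-category rank-sum tests for one pairwise metric.

    ``pairs`` is an iterable of PairwiseComparison records with values.
    Categories with fewer than ``min_n`` values are skipped (logged).
    BH correction is applied across the family of tests for this metric.
    """
    values: Dict[str, List[float]] = {}
    for p in pairs:
        if p.metric is not None and p.metric != metric:
            continue
        if p.value is None:
            continue
        values.setdefault(p.category, []).append(float(p.value))
    if aggregate_per_patient:
        per_patient: Dict[str, Dict[str, List[float]]] = {}
        for p in pairs:
            if (p.metric is not None and p.metric != metric) or p.value is None:
                continue
            per_patient.setdefault(p.category, {}).setdefault(p.patient_id, []).append(
                float(p.value)
            )
        values = {
            cat: [float(np.median(v)) for v in by_pat.values()]
            for cat, by_pat in per_patient.items()
        }
    skipped: List[str] = []
    usable = {}
    for cat, vals in values.items():
        if len(vals) < min_n:
            skipped.append(f"{cat}: only {len(vals)} value(s), need >= {min_n}")
        else:
            usable[cat] = vals
    cats = sorted(usable)
    results: List[GroupTestResult] = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            a, b = usable[cats[i]], usable[cats[j]]
            w, p = wilcoxon_rank_sum(a, b)
            results.append(
                GroupTestResult(
                    metric=metric,
                    category_a=cats[i],
                    category_b=cats[j],
                    n_a=len(a),
                    n_b=len(b),
                    statistic=w,
                    p_value=p,
                )
            )
    if results:
        adj = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return results, skipped
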