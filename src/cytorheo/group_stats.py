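"""Group comparison statistics: Wilcoxon rank-sum, boxplot summaries,
bundling-onset readout.

The rank-sum test is exact (full null enumeration) for tie-free samples with
both sizes at most 12, and otherwise uses the tie-corrected normal
approximation with continuity correction.  Significance stars follow the
convention *p <= 0.05, **p <= 0.01, ***p <= 0.001.  Box summaries use
linear-interpolation quantiles with whiskers at the furthest data points
within 1.5 IQR of the quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

EXACT_MAX_N = 12

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    for thresh, label in _STAR_THRESHOLDS:
        if p <= thresh:
            return label
    return "ns"


@dataclass
class TestResult:
    statistic: float          # rank sum of the first sample
    p_value: float
    method: Literal["exact", "normal_approx"]
    stars: str


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = (not has_ties) and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    ranks = stats.rankdata(combined)
    w = float(np.sum(ranks[:len(x)]))
    p = float(min(res.pvalue, 1.0))
    return TestResult(statistic=w, p_value=p,
                      method="exact" if exact else "normal_approx",
                      stars=stars_for_p(p))


def box_summary(x: Sequence[float]) -> BoxSummary:
    """Boxplot summary: linear-interpolation quartiles, whiskers extending no
    further than 1.5 IQR beyond them, anchored at actual data points."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=np.sort(x[(x < lo_fence) | (x > hi_fence)]))


def bundling_onset(concentrations: Sequence[float],
                   n_B_means: Sequence[float],
                   threshold_factor: float = 5.0) -> float | None:
    """Onset of cation-induced bundling.

    The onset is the smallest concentration whose mean bundle parameter
    exceeds ``threshold_factor`` times the low-concentration baseline (the
    mean of the first two points); ``None`` if never exceeded.
    """
    c = np.asarray(concentrations, dtype=float)
    nb = np.asarray(n_B_means, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 concentrations")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be ascending")
    baseline = np.mean(nb[:2])
    above = nb > threshold_factor * baseline
    if not above.any():
        return None
    return float(c[int(np.argmax(above))])
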