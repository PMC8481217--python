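"""Per-timepoint unpaired comparison between stent conditions.

At every measurement time point the across-experiment normalized wound
areas of the two conditions are compared with a classical two-sample
equal-variance Student t test (two-sided).  No multiple-testing
correction is applied across time points; each test stands alone, and
this is logged prominently.  Significance onset is reported as the
earliest time from which *all* subsequent time points are significant,
so isolated early crossings do not count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .quantify import NormalizedSeries

logger = logging.getLogger(__name__)

__all__ = ["TTestResult", "ComparisonResult", "unpaired_t_test", "compare_conditions"]


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


@dataclass(frozen=True)
class ComparisonResult:
    """Per-timepoint test results for two conditions on a common grid."""

    time_points: np.ndarray
    t_statistic: np.ndarray
    degrees_of_freedom: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    first_significant_time: float | None


def unpaired_t_test(sample_a, sample_b, equal_var: bool = True) -> TTestResult:
    """Classical unpaired two-sample t test (equal-variance Student by default).

    With equal variances assumed, df = n_a + n_b − 2 and the two-sided p
    comes from the central t distribution.  Degenerate zero-variance
    samples use the conventions p = 1 for equal means and p = 0 for
    unequal means.  Set ``equal_var=False`` for the Welch variant.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        df = a.size + b.size - 2
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t, df, 0.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def compare_conditions(
    curves_a: list[NormalizedSeries],
    curves_b: list[NormalizedSeries],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> ComparisonResult:
    """Test conditions a vs b at every time point of their common grid.

    ``first_significant_time`` is the earliest time point from which every
    subsequent time point has p < alpha (None when no such time exists).
    """
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValueError("need at least 2 experiments per condition")
    t = curves_a[0].time_points
    for s in list(curves_a) + list(curves_b):
        if not np.array_equal(s.time_points, t):
            raise ValueError("all series must share a common time grid")
    va = np.stack([s.normalized_area for s in curves_a])
    vb = np.stack([s.normalized_area for s in curves_b])
    results = [unpaired_t_test(va[:, i], vb[:, i], equal_var=equal_var)
               for i in range(t.size)]
    p = np.array([r.p_value for r in results])
    sig = p < alpha
    first = None
    if sig.size and sig[-1]:
        # suffix scan: earliest index from which everything is significant
        idx = sig.size - 1
        while idx > 0 and sig[idx - 1]:
            idx -= 1
        first = float(t[idx])
    logger.info("per-timepoint t tests: no multiple-testing correction applied "
                "(%d time points, alpha=%g)", t.size, alpha)
    return ComparisonResult(
        time_points=t,
        t_statistic=np.array([r.t_statistic for r in results]),
        degrees_of_freedom=np.array([r.degrees_of_freedom for r in results]),
        p_value=p,
        significant=sig,
        alpha=alpha,
        first_significant_time=first,
    )
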