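"""Distribution summaries for exponent estimates and weight comparisons.

Quartiles follow the linear-interpolation (type-7) convention, i.e. the
default of numpy/R, matching standard box-plot software.  Box whiskers extend
to the most extreme values within 1.5x the interquartile range of the
quartiles; points beyond are outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BoxSummary",
    "BiasSummary",
    "box_summary",
    "cliffs_delta",
    "ks_two_sample",
    "exponent_bias",
]


@dataclass(frozen=True)
class BoxSummary:
    q25: float
    median: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple

    @property
    def iqr_width(self) -> float:
        return self.q75 - self.q25


@dataclass(frozen=True)
class BiasSummary:
    bias: float           # mean(estimates) - truth
    median_error: float   # median(estimates) - truth
    q25: float
    q75: float


def box_summary(values) -> BoxSummary:
    """Five-number box-plot summary with 1.5*IQR whiskers."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("box_summary requires nonempty input")
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxSummary(
        q25=float(q25), median=float(med), q75=float(q75),
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) - P(x < y), computed exactly in O(n log n).

    Ties contribute zero.  +1 means complete separation with x above y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires nonempty samples")
    ys = np.sort(y)
    wins = np.searchsorted(ys, x, side="left").sum()          # y_j <  x_i
    losses = (y.size - np.searchsorted(ys, x, side="right")).sum()  # y_j > x_i
    return float((int(wins) - int(losses)) / (x.size * y.size))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample requires nonempty samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def exponent_bias(estimates, truth: float) -> BiasSummary:
    """Accuracy summary of replicate exponent estimates against the truth."""
    e = np.asarray(estimates, dtype=float)
    if e.size == 0:
        raise ValueError("exponent_bias requires nonempty estimates")
    q25, med, q75 = np.quantile(e, [0.25, 0.5, 0.75])
    return BiasSummary(
        bias=float(e.mean() - truth),
        median_error=float(med - truth),
        q25=float(q25),
        q75=float(q75),
    )
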