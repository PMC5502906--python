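"""Confidence intervals and the four-outcome classification.

Combining an equivalence test with the ordinary test against zero yields
four possible study outcomes: statistically equivalent only, statistically
different from zero only, both, or undetermined. The classification is a
pure function of two intervals — the (1 - 2*alpha) CI versus the bounds and
the (1 - alpha) CI versus zero — which at alpha = .05 are the familiar 90%
and 95% intervals.

"Inside the bounds" is an open-interval comparison: a CI endpoint exactly on
a bound corresponds to p = alpha, which does not reject.
"""

from __future__ import annotations

import math
from typing import Tuple

from scipy import special

from .model import (
    Bounds,
    CorrelationSummary,
    GroupSummary,
    OneSampleSummary,
    OutcomeCall,
    OutcomeCategory,
    PairedSummary,
    TostResult,
)
from .tost_corr_meta import fisher_z, fisher_z_inv
from .tost_means import pooled_sd, welch_df

__all__ = [
    "ci_mean_difference",
    "ci_paired",
    "ci_one_sample",
    "ci_correlation",
    "classify_outcome",
    "outcome_from_result",
    "render_intervals",
]

Interval = Tuple[float, float]


def _t_interval(est: float, se: float, df: float, level: float) -> Interval:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    if not se > 0:
        raise ValueError("degenerate standard error")
    q = float(special.stdtrit(df, 1.0 - (1.0 - level) / 2.0))
    return (est - q * se, est + q * se)


def ci_mean_difference(
    g1: GroupSummary, g2: GroupSummary, level: float = 0.90, var_equal: bool = False
) -> Interval:
    """Two-sided CI for the raw mean difference of two independent groups.

    SE and df follow the chosen test variant: pooled for Student,
    Welch–Satterthwaite otherwise.
    """
    est = g1.mean - g2.mean
    if var_equal:
        se = pooled_sd(g1, g2) * math.sqrt(1.0 / g1.n + 1.0 / g2.n)
        df: float = g1.n + g2.n - 2
    else:
        se = math.sqrt(g1.sd**2 / g1.n + g2.sd**2 / g2.n)
        df = welch_df(g1, g2)
    return _t_interval(est, se, df, level)


def ci_paired(p: PairedSummary, level: float = 0.90) -> Interval:
    """Two-sided CI for the mean of the paired difference scores."""
    return _t_interval(
        p.mean1 - p.mean2, p.sd_diff / math.sqrt(p.n_pairs), p.n_pairs - 1, level
    )


def ci_one_sample(s: OneSampleSummary, level: float = 0.90) -> Interval:
    """Two-sided CI for ``mean - mu``."""
    return _t_interval(s.mean - s.mu, s.sd / math.sqrt(s.n), s.n - 1, level)


def ci_correlation(c: CorrelationSummary, level: float = 0.90) -> Interval:
    """Two-sided CI for a correlation, Fisher-z based and back-transformed."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    q = float(special.ndtri(1.0 - (1.0 - level) / 2.0))
    se = 1.0 / math.sqrt(c.n - 3)
    z = fisher_z(c.r)
    return (fisher_z_inv(z - q * se), fisher_z_inv(z + q * se))


def classify_outcome(ci90: Interval, ci95: Interval, bounds: Bounds) -> OutcomeCall:
    """Map the two intervals to one of the four joint outcomes.

    equivalent  <=> the narrow CI lies strictly inside (low, high);
    different   <=> zero lies outside the wide CI.
    ``ci90`` must be nested inside ``ci95``.
    """
    if ci90[0] < ci95[0] or ci90[1] > ci95[1]:
        raise ValueError("the narrow CI must be contained in the wide CI")
    equivalent = bounds.low < ci90[0] and ci90[1] < bounds.high
    different = not (ci95[0] <= 0.0 <= ci95[1])
    category = {
        (True, False): OutcomeCategory.equivalent_only,
        (False, True): OutcomeCategory.different_only,
        (True, True): OutcomeCategory.equivalent_and_different,
        (False, False): OutcomeCategory.undetermined,
    }[(equivalent, different)]
    return OutcomeCall(category=category, ci90=ci90, ci95=ci95)


def outcome_from_result(res: TostResult) -> OutcomeCall:
    """Classify a TOST result with its own (1-2a)/(1-a) interval pair."""
    return classify_outcome(res.ci_narrow, res.ci_wide, res.bounds_raw)


def render_intervals(call: OutcomeCall, bounds: Bounds, width: int = 60) -> str:
    """ASCII bracket diagram of the CIs against the bounds and zero.

    The wide CI is drawn with ``-``, the narrow CI with ``=``, the point
    estimate with ``#``; ``L``/``U`` mark the bounds and ``0`` marks zero.
    """
    lo95, hi95 = call.ci95
    lo90, hi90 = call.ci90
    marks = [lo95, hi95, bounds.low, bounds.high, 0.0]
    span_lo = min(v for v in marks if math.isfinite(v))
    span_hi = max(v for v in marks if math.isfinite(v))
    pad = 0.1 * (span_hi - span_lo) or 1.0
    span_lo, span_hi = span_lo - pad, span_hi + pad

    def col(x: float) -> int:
        frac = (x - span_lo) / (span_hi - span_lo)
        return min(width - 1, max(0, round(frac * (width - 1))))

    row = [" "] * width
    for i in range(col(lo95), col(hi95) + 1):
        row[i] = "-"
    for i in range(col(lo90), col(hi90) + 1):
        row[i] = "="
    est = 0.5 * (lo90 + hi90)
    row[col(est)] = "#"
    axis = [" "] * width
    if math.isfinite(bounds.low):
        axis[col(bounds.low)] = "L"
    if math.isfinite(bounds.high):
        axis[col(bounds.high)] = "U"
    axis[col(0.0)] = "0"
    return "".join(row) + "\n" + "".join(axis)
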