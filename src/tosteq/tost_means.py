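"""TOST equivalence tests for mean differences.

Implements the two one-sided tests procedure for independent means (Student
and Welch variants), paired means, and one-sample designs, plus the helpers
that move equivalence bounds between raw and standardized scales.

The TOST logic is shared: with signed bounds (low, high) and an estimated
effect ``est`` with standard error ``se``,

    stat_low  = (est - low) / se      (tested in the upper tail)
    stat_high = (est - high) / se     (tested in the lower tail)

and equivalence is declared at level alpha when both one-sided tests reject,
i.e. when the true effect can be placed strictly inside (low, high). An
infinite bound turns the procedure into a one-sided inferiority/superiority
test: the statistic against the infinite bound is infinitely significant and
its p value is 0 by convention, so the headline p is the finite-bound p.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Optional, Tuple

from scipy import special

from .model import (
    BoundScale,
    Bounds,
    GroupSummary,
    OneSampleSummary,
    PairedSummary,
    TostResult,
    check_alpha,
)

__all__ = [
    "pooled_sd",
    "welch_df",
    "tost_independent",
    "tost_paired",
    "tost_one_sample",
    "convert_bounds",
    "ConversionDirection",
]


def _t_sf(x: float, df: float) -> float:
    """Upper-tail probability of a central t variate; handles +/-inf."""
    if math.isinf(x):
        return 0.0 if x > 0 else 1.0
    return float(special.stdtr(df, -x))


def _t_cdf(x: float, df: float) -> float:
    if math.isinf(x):
        return 1.0 if x > 0 else 0.0
    return float(special.stdtr(df, x))


def _t_ppf(q: float, df: float) -> float:
    return float(special.stdtrit(df, q))


def _norm_sf(x: float) -> float:
    if math.isinf(x):
        return 0.0 if x > 0 else 1.0
    return float(special.ndtr(-x))


def _norm_cdf(x: float) -> float:
    if math.isinf(x):
        return 1.0 if x > 0 else 0.0
    return float(special.ndtr(x))


def tost_from_estimate(
    est: float,
    se: float,
    df: Optional[float],
    bounds_raw: Bounds,
    alpha: float,
) -> TostResult:
    """Assemble a :class:`TostResult` from an estimate and its SE.

    ``df=None`` selects the standard normal reference distribution (used by
    the correlation and meta-analytic tests); otherwise a central t with
    ``df`` degrees of freedom. ``bounds_raw`` must be on the same scale as
    ``est``.
    """
    check_alpha(alpha)
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")

    low, high = bounds_raw.low, bounds_raw.high
    stat_low = math.inf if math.isinf(low) else (est - low) / se
    stat_high = -math.inf if math.isinf(high) else (est - high) / se

    if df is None:
        p_low = _norm_sf(stat_low)
        p_high = _norm_cdf(stat_high)
        q_narrow = float(special.ndtri(1.0 - alpha))
        q_wide = float(special.ndtri(1.0 - alpha / 2.0))
    else:
        if not df > 0:
            raise ValueError(f"degrees of freedom must be positive, got {df}")
        p_low = _t_sf(stat_low, df)
        p_high = _t_cdf(stat_high, df)
        q_narrow = _t_ppf(1.0 - alpha, df)
        q_wide = _t_ppf(1.0 - alpha / 2.0, df)

    # headline p: largest one-sided p over the finite bounds only
    finite_ps = [p for p, b in ((p_low, low), (p_high, high)) if math.isfinite(b)]
    p_tost = max(finite_ps)

    return TostResult(
        stat_low=stat_low,
        stat_high=stat_high,
        df=df,
        p_low=p_low,
        p_high=p_high,
        p_tost=p_tost,
        ci_narrow=(est - q_narrow * se, est + q_narrow * se),
        ci_wide=(est - q_wide * se, est + q_wide * se),
        alpha=alpha,
        equivalent=(p_low < alpha and p_high < alpha),
        bounds_raw=bounds_raw,
    )


def pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    """Pooled standard deviation of two independent groups.

    ``sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2))``; this is the
    standardizer behind Cohen's d for two-group designs.
    """
    num = (g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2
    return math.sqrt(num / (g1.n + g2.n - 2))


def welch_df(g1: GroupSummary, g2: GroupSummary) -> float:
    """Welch–Satterthwaite degrees of freedom (fractional, never rounded)."""
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    return (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))


class ConversionDirection(str, Enum):
    to_raw = "to_raw"
    to_standardized = "to_standardized"


def convert_bounds(
    bounds: Bounds,
    standardizer: float,
    direction: ConversionDirection | str,
    standardized_scale: BoundScale = BoundScale.cohen_d,
) -> Bounds:
    """Convert bounds between raw units and a standardized scale.

    ``to_raw`` multiplies both endpoints by ``standardizer`` (Δ = d × σ);
    ``to_standardized`` divides (d = Δ / σ). Infinite endpoints are
    preserved. The scale tag becomes ``raw`` or ``standardized_scale``.
    """
    direction = ConversionDirection(direction)
    if not standardizer > 0:
        raise ValueError(f"standardizer must be positive, got {standardizer}")

    def _conv(x: float) -> float:
        if math.isinf(x):
            return x
        return x * standardizer if direction is ConversionDirection.to_raw else x / standardizer

    scale = BoundScale.raw if direction is ConversionDirection.to_raw else standardized_scale
    return Bounds(low=_conv(bounds.low), high=_conv(bounds.high), scale=scale)


def _bounds_to_raw(bounds: Bounds, standardizer: float, accepted: tuple[BoundScale, ...]) -> Bounds:
    if bounds.scale is BoundScale.raw:
        return bounds
    if bounds.scale in accepted:
        return convert_bounds(bounds, standardizer, ConversionDirection.to_raw)
    raise ValueError(
        f"bounds on scale '{bounds.scale.value}' are not valid for this design; "
        f"expected raw or one of {[s.value for s in accepted]}"
    )


def tost_independent(
    g1: GroupSummary,
    g2: GroupSummary,
    bounds: Bounds,
    alpha: float = 0.05,
    var_equal: bool = False,
) -> TostResult:
    """TOST for the difference between two independent means.

    With ``var_equal=True`` the Student variant is used: the pooled SD sets
    the standard error ``sigma_p * sqrt(1/n1 + 1/n2)`` with
    ``df = n1 + n2 - 2``. Otherwise (the default, recommended whenever group
    sizes differ) the Welch variant uses ``sqrt(sd1^2/n1 + sd2^2/n2)`` with
    Welch–Satterthwaite df.

    Cohen's-d bounds are converted to raw units with the pooled SD for both
    variants, so the meaning of a standardized bound does not depend on the
    variance assumption.
    """
    sp = pooled_sd(g1, g2)
    bounds_raw = _bounds_to_raw(bounds, sp, (BoundScale.cohen_d,))
    est = g1.mean - g2.mean
    if var_equal:
        se = sp * math.sqrt(1.0 / g1.n + 1.0 / g2.n)
        df: float = g1.n + g2.n - 2
    else:
        se = math.sqrt(g1.sd**2 / g1.n + g2.sd**2 / g2.n)
        df = welch_df(g1, g2)
    return tost_from_estimate(est, se, df, bounds_raw, alpha)


def tost_paired(p: PairedSummary, bounds: Bounds, alpha: float = 0.05) -> TostResult:
    """TOST for the mean difference of paired observations.

    The correlation between the pairs enters through the SD of the
    difference scores: ``SE = SD_diff / sqrt(n)`` with ``df = n - 1``.
    Cohen's-d_z bounds are converted to raw units via SD_diff.
    """
    bounds_raw = _bounds_to_raw(bounds, p.sd_diff, (BoundScale.cohen_dz,))
    est = p.mean1 - p.mean2
    se = p.sd_diff / math.sqrt(p.n_pairs)
    return tost_from_estimate(est, se, p.n_pairs - 1, bounds_raw, alpha)


def tost_one_sample(s: OneSampleSummary, bounds: Bounds, alpha: float = 0.05) -> TostResult:
    """TOST for a single mean against a reference value ``mu``.

    The tested effect is ``mean - mu`` with ``SE = sd / sqrt(n)`` and
    ``df = n - 1``; Cohen's-d bounds are standardized by the sample SD.
    """
    bounds_raw = _bounds_to_raw(bounds, s.sd, (BoundScale.cohen_d,))
    est = s.mean - s.mu
    se = s.sd / math.sqrt(s.n)
    return tost_from_estimate(est, se, s.n - 1, bounds_raw, alpha)
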