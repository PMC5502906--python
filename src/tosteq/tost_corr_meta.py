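"""TOST equivalence tests for correlations and meta-analytic effect sizes.

The correlation test works on Fisher's z scale, where the transformed
statistic is approximately normal with standard error ``1/sqrt(n - 3)``. The
meta-analytic test is a plain z test of the pooled effect against each bound
using the meta-analytic standard error (the pooling itself is the job of
meta-analysis software; only its summary output enters here).
"""

from __future__ import annotations

import math

from .model import BoundScale, Bounds, CorrelationSummary, MetaEffect, TostResult
from .tost_means import tost_from_estimate

__all__ = ["fisher_z", "fisher_z_inv", "r_to_d", "d_to_r", "tost_correlation", "tost_meta"]


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, ``ln((1+r)/(1-r))/2``."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"Fisher z requires |r| < 1, got {r}")
    return math.atanh(r)


def fisher_z_inv(z: float) -> float:
    """Inverse Fisher transform (tanh)."""
    return math.tanh(z)


def r_to_d(r: float) -> float:
    """Convert a correlation to Cohen's d: ``2r / sqrt(1 - r^2)``."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"r must satisfy |r| < 1, got {r}")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def d_to_r(d: float) -> float:
    """Inverse of :func:`r_to_d`: ``d / sqrt(d^2 + 4)``."""
    return d / math.sqrt(d * d + 4.0)


def tost_correlation(
    c: CorrelationSummary, bounds: Bounds, alpha: float = 0.05
) -> TostResult:
    """TOST for an observed correlation against r-scale bounds.

    Statistics are ``(z(r) - z(r_bound)) * sqrt(n - 3)`` referred to the
    standard normal; both confidence intervals are computed on the z scale
    and back-transformed to the r scale. ``bounds_raw`` in the result keeps
    the r-scale bounds, so the CI/TOST duality reads directly on the r scale
    (the transform is strictly monotone).
    """
    if bounds.scale is not BoundScale.correlation:
        raise ValueError(
            f"correlation test requires bounds on the correlation scale, "
            f"got '{bounds.scale.value}'"
        )
    se = 1.0 / math.sqrt(c.n - 3)
    z_bounds = Bounds(low=fisher_z(bounds.low), high=fisher_z(bounds.high), scale=BoundScale.raw)
    res = tost_from_estimate(fisher_z(c.r), se, None, z_bounds, alpha)
    return res.model_copy(
        update={
            "ci_narrow": tuple(fisher_z_inv(v) for v in res.ci_narrow),
            "ci_wide": tuple(fisher_z_inv(v) for v in res.ci_wide),
            "bounds_raw": bounds,
        }
    )


def tost_meta(m: MetaEffect, bounds: Bounds, alpha: float = 0.05) -> TostResult:
    """TOST for a meta-analytic effect size (Cohen's d or Hedges' g).

    ``Z = (effect - bound)/SE`` for each signed bound, referred to the
    standard normal. Equivalently: the effect is statistically equivalent
    when the (1 - 2*alpha) CI (90% at alpha = .05) falls inside the bounds.
    Bounds must be on the same standardized metric as the effect.
    """
    if bounds.scale is BoundScale.correlation:
        raise ValueError("meta-analytic test expects effect-size bounds, not correlation bounds")
    return tost_from_estimate(m.effect, m.se, None, bounds, alpha)
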