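"""Domain types shared by all equivalence-testing operations.

Every statistical routine in this package works from summary statistics, so
the types here are thin validated records: group summaries for the mean-based
designs, an observed correlation, a meta-analytic effect with its standard
error, the signed equivalence bounds, and the result containers.

All types are immutable pydantic models. They serialize to JSON with full
float precision, including infinite bounds (``Infinity`` constants), which is
the wire format used by the command-line interface.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Optional, Tuple, TypeVar

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "BoundScale",
    "Bounds",
    "GroupSummary",
    "PairedSummary",
    "OneSampleSummary",
    "CorrelationSummary",
    "MetaEffect",
    "TostResult",
    "OutcomeCategory",
    "OutcomeCall",
    "validate",
]

_CONFIG = ConfigDict(frozen=True, extra="forbid", ser_json_inf_nan="constants")


class BoundScale(str, Enum):
    """Scale on which a pair of equivalence bounds is expressed.

    ``raw``
        Measurement units of the outcome (e.g. scale points).
    ``cohen_d``
        Standardized mean difference; the standardizer is the pooled SD for
        two-group designs and the sample SD for one-sample designs.
    ``cohen_dz``
        Standardized difference for paired designs; the standardizer is the
        SD of the difference scores.
    ``correlation``
        Bounds on the correlation coefficient itself.
    """

    raw = "raw"
    cohen_d = "cohen_d"
    cohen_dz = "cohen_dz"
    correlation = "correlation"


class Bounds(BaseModel):
    """Signed lower/upper equivalence bounds.

    Bounds are always stored signed (``low`` typically negative) and all test
    statistics subtract the signed bound. One endpoint may be infinite
    (``low = -inf`` or ``high = +inf``, not both) to express an inferiority /
    superiority test against a single bound.
    """

    model_config = _CONFIG

    low: float
    high: float
    scale: BoundScale = BoundScale.raw

    @model_validator(mode="after")
    def _check(self) -> "Bounds":
        if math.isnan(self.low) or math.isnan(self.high):
            raise ValueError("bounds must not be NaN")
        if not self.low < self.high:
            raise ValueError(
                f"lower bound must be strictly below upper bound, got "
                f"low={self.low} >= high={self.high}"
            )
        if math.isinf(self.low) and math.isinf(self.high):
            raise ValueError("at most one bound may be infinite")
        if math.isinf(self.low) and self.low > 0:
            raise ValueError("an infinite lower bound must be -inf")
        if math.isinf(self.high) and self.high < 0:
            raise ValueError("an infinite upper bound must be +inf")
        if self.scale is BoundScale.correlation:
            if not (-1.0 < self.low < self.high < 1.0):
                raise ValueError(
                    "correlation-scale bounds must lie strictly inside (-1, 1)"
                )
        return self

    @property
    def two_sided(self) -> bool:
        """True when both bounds are finite (a genuine equivalence test)."""
        return math.isfinite(self.low) and math.isfinite(self.high)

    @classmethod
    def symmetric(cls, magnitude: float, scale: BoundScale = BoundScale.raw) -> "Bounds":
        """Bounds ``(-magnitude, +magnitude)`` on the given scale."""
        if not magnitude > 0:
            raise ValueError(f"bound magnitude must be positive, got {magnitude}")
        return cls(low=-magnitude, high=magnitude, scale=scale)


class GroupSummary(BaseModel):
    """Sample size, mean and SD of one independent group."""

    model_config = _CONFIG

    n: int
    mean: float
    sd: float

    @model_validator(mode="after")
    def _check(self) -> "GroupSummary":
        if self.n < 2:
            raise ValueError(f"group size n must be at least 2, got {self.n}")
        if not self.sd > 0:
            raise ValueError(f"group sd must be positive, got {self.sd}")
        return self


class PairedSummary(BaseModel):
    """Summary statistics for a paired (within-subject) design.

    ``r`` is the correlation between the two sets of observations; the SD of
    the difference scores is derived as
    ``sqrt(sd1^2 + sd2^2 - 2 r sd1 sd2)``.
    """

    model_config = _CONFIG

    n_pairs: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    r: float

    @model_validator(mode="after")
    def _check(self) -> "PairedSummary":
        if self.n_pairs < 2:
            raise ValueError(f"number of pairs must be at least 2, got {self.n_pairs}")
        if not self.sd1 > 0 or not self.sd2 > 0:
            raise ValueError("paired sds must be positive")
        if not -1.0 < self.r < 1.0:
            raise ValueError(f"pair correlation must satisfy |r| < 1, got {self.r}")
        if not self.sd_diff > 0:
            raise ValueError("derived SD of difference scores is zero")
        return self

    @property
    def sd_diff(self) -> float:
        return math.sqrt(
            self.sd1**2 + self.sd2**2 - 2.0 * self.r * self.sd1 * self.sd2
        )


class OneSampleSummary(BaseModel):
    """One-sample summary tested against a reference value ``mu``."""

    model_config = _CONFIG

    n: int
    mean: float
    sd: float
    mu: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "OneSampleSummary":
        if self.n < 2:
            raise ValueError(f"sample size n must be at least 2, got {self.n}")
        if not self.sd > 0:
            raise ValueError(f"sample sd must be positive, got {self.sd}")
        return self


class CorrelationSummary(BaseModel):
    """Observed correlation with its sample size.

    Requires ``n >= 4`` because the Fisher-z sampling variance is
    ``1/(n - 3)``.
    """

    model_config = _CONFIG

    n: int
    r: float

    @model_validator(mode="after")
    def _check(self) -> "CorrelationSummary":
        if self.n < 4:
            raise ValueError(
                f"correlation test needs n >= 4 (Fisher variance 1/(n-3)), got {self.n}"
            )
        if not -1.0 < self.r < 1.0:
            raise ValueError(f"correlation must satisfy |r| < 1, got {self.r}")
        return self


class MetaEffect(BaseModel):
    """Meta-analytic effect size (Cohen's d or Hedges' g) and its SE."""

    model_config = _CONFIG

    effect: float
    se: float

    @model_validator(mode="after")
    def _check(self) -> "MetaEffect":
        if not self.se > 0:
            raise ValueError(f"meta-analytic standard error must be positive, got {self.se}")
        return self


class TostResult(BaseModel):
    """Result of a TOST equivalence test.

    ``stat_low``/``stat_high`` are the statistics against the lower and upper
    bound; ``p_low`` is the upper-tail one-sided p of ``stat_low`` and
    ``p_high`` the lower-tail one-sided p of ``stat_high``. The headline TOST
    p value is the larger of the two one-sided p values (over the finite
    bounds). ``df`` is ``None`` for z-based tests (correlation, meta).

    ``ci_narrow`` is the (1 - 2*alpha) confidence interval whose containment
    inside the bounds is dual to the equivalence decision; ``ci_wide`` is the
    ordinary (1 - alpha) two-sided interval used for the test against zero.
    For correlation tests both intervals are back-transformed to the r scale
    and ``bounds_raw`` holds the r-scale bounds.
    """

    model_config = _CONFIG

    stat_low: float
    stat_high: float
    df: Optional[float]
    p_low: float
    p_high: float
    p_tost: float
    ci_narrow: Tuple[float, float]
    ci_wide: Tuple[float, float]
    alpha: float
    equivalent: bool
    bounds_raw: Bounds


class OutcomeCategory(str, Enum):
    """Joint outcome of the equivalence test and the test against zero."""

    equivalent_only = "equivalent_only"
    different_only = "different_only"
    equivalent_and_different = "equivalent_and_different"
    undetermined = "undetermined"


class OutcomeCall(BaseModel):
    """Four-way classification with the intervals that produced it."""

    model_config = _CONFIG

    category: OutcomeCategory
    ci90: Tuple[float, float]
    ci95: Tuple[float, float]


_M = TypeVar("_M", bound=BaseModel)


def validate(summary: _M) -> _M:
    """Re-run all invariant checks on ``summary`` and return it unchanged.

    Validation is idempotent: models are validated on construction, so this
    is mainly useful for values deserialized or assembled programmatically.
    Raises ``pydantic.ValidationError`` naming the violated invariant.
    """
    return type(summary).model_validate(summary.model_dump())


def check_alpha(alpha: float) -> float:
    """Validate a one-sided significance level, ``0 < alpha < 0.5``."""
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")
    return alpha
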