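"""Monte Carlo validation of the TOST operating characteristics.

Generates synthetic raw data (normal two-group, bivariate-normal paired and
correlation designs, normal one-sample) at a specified standardized true
effect, runs the package's own equivalence tests on the per-replication
summary statistics, and estimates the rejection (equivalence-declaration)
rate. Because the analytic power functions claim the same quantity, the two
routes cross-validate each other: at a true effect equal to a bound the rate
should sit at the alpha level, and at interior effects it should match the
noncentral-t power.

Seeding is counter-based: each replication draws from a generator keyed on
``(seed, rep_index)``, so a given replication's data are independent of
execution order and of how many replications are requested.
"""

from __future__ import annotations

import math
from typing import Tuple, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .model import (
    Bounds,
    CorrelationSummary,
    GroupSummary,
    OneSampleSummary,
    PairedSummary,
    check_alpha,
)
from .power import Design
from .tost_corr_meta import tost_correlation
from .tost_means import tost_independent, tost_one_sample, tost_paired

__all__ = ["SimScenario", "SimResult", "draw_summary", "rejection_rate"]

Summary = Union[
    Tuple[GroupSummary, GroupSummary], PairedSummary, OneSampleSummary, CorrelationSummary
]


class SimScenario(BaseModel):
    """One Monte Carlo condition.

    ``n`` counts observations per group (independent), pairs (paired),
    observations (one-sample) or total N (correlation). ``true_effect`` is
    standardized: Cohen's d for independent groups (standardizer
    ``sqrt((sd1^2+sd2^2)/2)``), d_z for pairs (standardizer the population
    SD of the difference scores), d for one-sample, and the population
    correlation itself for the correlation design.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    design: Design
    n: int
    true_effect: float = 0.0
    sd1: float = 1.0
    sd2: float = 1.0
    r_pairs: float = 0.5
    bounds: Bounds
    alpha: float = 0.05
    reps: int = 1000
    seed: int = 0
    var_equal: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SimScenario":
        if self.n < 4 if self.design is Design.correlation else self.n < 2:
            raise ValueError(f"n={self.n} too small for design '{self.design.value}'")
        if not self.sd1 > 0 or not self.sd2 > 0:
            raise ValueError("scenario sds must be positive")
        if not -1.0 < self.r_pairs < 1.0:
            raise ValueError(f"pair correlation must satisfy |r| < 1, got {self.r_pairs}")
        if self.design is Design.correlation and not -1.0 < self.true_effect < 1.0:
            raise ValueError("correlation true effect must lie in (-1, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        check_alpha(self.alpha)
        return self


class SimResult(BaseModel):
    """Empirical rejection rate with its binomial standard error."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    rate: float
    se: float
    reps: int


def _rng(seed: int, rep_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, rep_index])


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def draw_summary(s: SimScenario, rep_index: int) -> Summary:
    """Summary statistics of one freshly drawn replication.

    Deterministic in ``(s.seed, rep_index)``.
    """
    rng = _rng(s.seed, rep_index)
    if s.design is Design.independent:
        delta = s.true_effect * math.sqrt((s.sd1**2 + s.sd2**2) / 2.0)
        x1 = rng.normal(delta, s.sd1, s.n)
        x2 = rng.normal(0.0, s.sd2, s.n)
        return (
            GroupSummary(n=s.n, mean=float(np.mean(x1)), sd=_sample_sd(x1)),
            GroupSummary(n=s.n, mean=float(np.mean(x2)), sd=_sample_sd(x2)),
        )
    if s.design is Design.paired:
        sd_diff = math.sqrt(
            s.sd1**2 + s.sd2**2 - 2.0 * s.r_pairs * s.sd1 * s.sd2
        )
        delta = s.true_effect * sd_diff
        z1 = rng.standard_normal(s.n)
        z2 = rng.standard_normal(s.n)
        x1 = delta + s.sd1 * z1
        x2 = s.sd2 * (s.r_pairs * z1 + math.sqrt(1.0 - s.r_pairs**2) * z2)
        r_obs = float(np.corrcoef(x1, x2)[0, 1])
        return PairedSummary(
            n_pairs=s.n,
            mean1=float(np.mean(x1)),
            mean2=float(np.mean(x2)),
            sd1=_sample_sd(x1),
            sd2=_sample_sd(x2),
            r=r_obs,
        )
    if s.design is Design.one_sample:
        x = rng.normal(s.true_effect * s.sd1, s.sd1, s.n)
        return OneSampleSummary(n=s.n, mean=float(np.mean(x)), sd=_sample_sd(x), mu=0.0)
    # correlation: standard bivariate normal with rho = true_effect
    rho = s.true_effect
    z1 = rng.standard_normal(s.n)
    z2 = rng.standard_normal(s.n)
    x1 = z1
    x2 = rho * z1 + math.sqrt(1.0 - rho**2) * z2
    return CorrelationSummary(n=s.n, r=float(np.corrcoef(x1, x2)[0, 1]))


def _equivalent(s: SimScenario, summary: Summary) -> bool:
    if s.design is Design.independent:
        g1, g2 = summary
        return tost_independent(g1, g2, s.bounds, s.alpha, var_equal=s.var_equal).equivalent
    if s.design is Design.paired:
        return tost_paired(summary, s.bounds, s.alpha).equivalent
    if s.design is Design.one_sample:
        return tost_one_sample(summary, s.bounds, s.alpha).equivalent
    return tost_correlation(summary, s.bounds, s.alpha).equivalent


def rejection_rate(s: SimScenario) -> SimResult:
    """Fraction of replications in which the TOST declares equivalence.

    Each replication draws fresh data via :func:`draw_summary` and runs the
    corresponding equivalence test from this package at the scenario's
    bounds and alpha. The attached standard error is the binomial
    ``sqrt(p(1-p)/reps)``.
    """
    hits = 0
    for rep in range(s.reps):
        if _equivalent(s, draw_summary(s, rep)):
            hits += 1
    rate = hits / s.reps
    return SimResult(rate=rate, se=math.sqrt(rate * (1.0 - rate) / s.reps), reps=s.reps)
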