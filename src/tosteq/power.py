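"""Power analysis and bound-setting helpers for equivalence tests.

Two sample-size paths are provided. The normal approximation assumes a true
effect of zero and gives, per independent group,

    n = 2 (z_alpha + z_{beta/2})^2 / delta^2

for a standardized bound delta (half that count in pairs/observations for
paired and one-sample designs). The exact path evaluates the probability
that both one-sided tests reject — the difference of two noncentral-t CDFs
at the critical value, with noncentrality ``(true_effect - bound)/se_unit``
— and searches for the smallest n reaching the requested power. The exact
path also accepts nonzero true effects.

Bound-setting helpers translate resource limits into a smallest effect size
of interest (sensitivity analysis), implement the small-telescopes rule
(the effect an original study had 33% power to detect), and provide the
conventional small/medium/large benchmarks for d, d_z and r.
"""

from __future__ import annotations

import math
from enum import Enum

from scipy import optimize, special, stats

from .model import BoundScale, Bounds, check_alpha
from .tost_corr_meta import d_to_r, fisher_z, r_to_d
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Design",
    "PowerQuery",
    "PowerResult",
    "n_approx",
    "power_exact",
    "n_exact",
    "nhst_power",
    "nhst_n",
    "min_detectable",
    "small_telescopes_bound",
    "benchmark_bounds",
]

_N_CAP = 10**7


class Design(str, Enum):
    independent = "independent"
    paired = "paired"
    one_sample = "one_sample"
    correlation = "correlation"


class PowerQuery(BaseModel):
    """A priori sample-size question for an equivalence test."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    design: Design
    alpha: float = 0.05
    power: float = 0.80
    bounds: Bounds
    true_effect: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "PowerQuery":
        check_alpha(self.alpha)
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must lie in (0, 1), got {self.power}")
        return self


class PowerResult(BaseModel):
    """Required sample size with the power actually achieved at that size.

    ``n_per_group`` counts observations per group for independent designs,
    pairs for paired designs, observations for one-sample designs, and the
    total N for correlations.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_per_group: int
    method: str  # "approximation" | "exact"
    achieved_power: float


def _zq(p: float) -> float:
    return float(special.ndtri(p))


def _nct_cdf(x: float, df: float, ncp: float) -> float:
    # scipy's noncentral-t CDF underflows to NaN far in the tail; those
    # regions contribute 0 or 1 depending on the side of the mode
    v = float(stats.nct.cdf(x, df, ncp))
    if math.isnan(v):
        return 0.0 if x < ncp else 1.0
    return v


def _min_n(design: Design) -> int:
    return 4 if design is Design.correlation else 2


def _require_finite(bounds: Bounds) -> None:
    if not bounds.two_sided:
        raise ValueError("sample-size planning requires two finite equivalence bounds")


def n_approx(q: PowerQuery) -> PowerResult:
    """Required sample size from the normal approximation (true effect 0).

    Evaluated per bound; the result is the larger requirement, rounded up.
    Correlation bounds are first converted from r to Cohen's d, following
    the G*Power convention for point-biserial effects, so the total N is
    ``4 (z_alpha + z_{beta/2})^2 / d^2``.
    """
    if q.true_effect != 0.0:
        raise ValueError(
            "the normal approximation assumes a true effect of zero; "
            "use n_exact for a nonzero expected effect"
        )
    _require_finite(q.bounds)
    zsum = _zq(1.0 - q.alpha) + _zq(1.0 - (1.0 - q.power) / 2.0)

    def _n_for(bound: float) -> float:
        if q.design is Design.correlation:
            d = r_to_d(bound)
            return 4.0 * zsum**2 / d**2
        per_group = 2.0 * zsum**2 / bound**2
        if q.design is Design.independent:
            return per_group
        return per_group / 2.0  # pairs/observations: half the per-group count

    n_raw = max(_n_for(q.bounds.low), _n_for(q.bounds.high))
    n = max(_min_n(q.design), math.ceil(n_raw - 1e-9))
    achieved = power_exact(q.design, n, q.alpha, q.bounds, q.true_effect)
    return PowerResult(n_per_group=n, method="approximation", achieved_power=achieved)


def power_exact(
    design: Design | str,
    n: int,
    alpha: float,
    bounds: Bounds,
    true_effect: float = 0.0,
) -> float:
    """Probability that both one-sided tests reject (exact TOST power).

    For the t-based designs this is
    ``max(0, F_nt(-t_crit; df, ncp_U) - F_nt(t_crit; df, ncp_L))`` with
    ``ncp_X = (true_effect - bound_X)/se_unit`` and ``se_unit = sqrt(2/n)``
    per independent group or ``sqrt(1/n)`` for paired/one-sample designs
    (effects and bounds standardized as d or d_z). For correlations the
    computation is on the Fisher-z scale with SE ``1/sqrt(n - 3)`` against
    the standard normal. One infinite bound gives the one-sided
    (inferiority/superiority) power; two infinite bounds are rejected.
    """
    design = Design(design)
    check_alpha(alpha)
    if math.isinf(bounds.low) and math.isinf(bounds.high):
        raise ValueError("power is undefined with both bounds infinite")
    if n < _min_n(design):
        raise ValueError(f"n={n} too small for design '{design.value}'")

    if design is Design.correlation:
        zcrit = _zq(1.0 - alpha)
        scale = math.sqrt(n - 3)
        zt = fisher_z(true_effect)
        p_hi = (
            1.0
            if math.isinf(bounds.high)
            else float(special.ndtr(-zcrit - (zt - fisher_z(bounds.high)) * scale))
        )
        p_lo_cdf = (
            0.0
            if math.isinf(bounds.low)
            else float(special.ndtr(zcrit - (zt - fisher_z(bounds.low)) * scale))
        )
        return max(0.0, p_hi - p_lo_cdf)

    if design is Design.independent:
        df = 2 * n - 2
        se_unit = math.sqrt(2.0 / n)
    else:
        df = n - 1
        se_unit = math.sqrt(1.0 / n)
    tcrit = float(special.stdtrit(df, 1.0 - alpha))
    upper = (
        1.0
        if math.isinf(bounds.high)
        else _nct_cdf(-tcrit, df, (true_effect - bounds.high) / se_unit)
    )
    lower = (
        0.0
        if math.isinf(bounds.low)
        else _nct_cdf(tcrit, df, (true_effect - bounds.low) / se_unit)
    )
    return max(0.0, upper - lower)


def n_exact(q: PowerQuery) -> PowerResult:
    """Smallest n whose exact TOST power reaches the requested power.

    Bracket by doubling, then bisect on the integer n. The returned result
    satisfies ``power(n) >= power`` and ``power(n - 1) < power``.
    """
    _require_finite(q.bounds)
    if not (q.bounds.low < q.true_effect < q.bounds.high):
        raise ValueError(
            "true effect must lie strictly inside the bounds for equivalence "
            "power to approach 1"
        )

    def _pw(n: int) -> float:
        return power_exact(q.design, n, q.alpha, q.bounds, q.true_effect)

    lo = _min_n(q.design)
    hi = lo
    while _pw(hi) < q.power:
        hi *= 2
        if hi > _N_CAP:
            raise ValueError(
                f"requested power {q.power} not reachable below n = {_N_CAP}; "
                "the bounds are too close to the true effect"
            )
    # power is nondecreasing in n over the bracket; bisect for the smallest n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _pw(mid) >= q.power:
            hi = mid
        else:
            lo = mid
    n = hi if _pw(lo) < q.power else lo
    return PowerResult(n_per_group=n, method="exact", achieved_power=_pw(n))


def nhst_power(design: Design | str, n: int, d: float, alpha: float) -> float:
    """Power of the ordinary two-sided t test at effect size d.

    ``design`` independent: two-group test, n per group, ncp = d*sqrt(n/2);
    paired/one_sample: ncp = d*sqrt(n), df = n - 1.
    """
    design = Design(design)
    if design is Design.independent:
        df = 2 * n - 2
        ncp = d * math.sqrt(n / 2.0)
    elif design in (Design.paired, Design.one_sample):
        df = n - 1
        ncp = d * math.sqrt(n)
    else:
        raise ValueError("NHST power supports mean-based designs only")
    tcrit = float(special.stdtrit(df, 1.0 - alpha / 2.0))
    return 1.0 - _nct_cdf(tcrit, df, ncp) + _nct_cdf(-tcrit, df, ncp)


def nhst_n(d: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Per-group n for a two-sided independent t test to detect d.

    Iterative noncentral-t search; the smallest n with power at or above the
    target.
    """
    if d == 0:
        raise ValueError("effect size d must be nonzero")
    check_alpha(alpha)
    d = abs(d)
    lo, hi = 2, 2
    while nhst_power(Design.independent, hi, d, alpha) < power:
        hi *= 2
        if hi > _N_CAP:
            raise ValueError("required sample size exceeds the search cap")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if nhst_power(Design.independent, mid, d, alpha) >= power:
            hi = mid
        else:
            lo = mid
    return hi if nhst_power(Design.independent, lo, d, alpha) < power else lo


class SensitivityMode(str, Enum):
    nhst = "nhst"
    equivalence = "equivalence"


def min_detectable(
    design: Design | str,
    n: int,
    alpha: float = 0.05,
    power: float = 0.80,
    mode: SensitivityMode | str = SensitivityMode.equivalence,
) -> float:
    """Sensitivity analysis: the effect size a fixed-n study resolves.

    ``mode="equivalence"``: the symmetric standardized bound magnitude at
    which the equivalence test has the stated power under a true effect of
    zero, by closed-form inversion of the normal approximation
    (``delta = sqrt(2) (z_alpha + z_{beta/2}) / sqrt(n)`` per independent
    group; drop the sqrt(2) for paired/one-sample). With no practical or
    theoretical bound available, this is the natural resource-based SESOI.

    ``mode="nhst"``: the smallest d detectable with the stated power in an
    ordinary two-sided t test (root-finding on the noncentral-t power
    function). For correlations the equivalence inversion is mapped back to
    the r scale through the d-to-r conversion.
    """
    design = Design(design)
    mode = SensitivityMode(mode)
    check_alpha(alpha)
    if n < 3:
        raise ValueError(f"sensitivity analysis needs n >= 3, got {n}")
    zsum = _zq(1.0 - alpha) + _zq(1.0 - (1.0 - power) / 2.0)
    if mode is SensitivityMode.equivalence:
        if design is Design.independent:
            return math.sqrt(2.0) * zsum / math.sqrt(n)
        if design in (Design.paired, Design.one_sample):
            return zsum / math.sqrt(n)
        return d_to_r(2.0 * zsum / math.sqrt(n))
    if design is Design.correlation:
        raise ValueError("NHST sensitivity is defined for mean-based designs")
    f = lambda d: nhst_power(design, n, d, alpha) - power
    return float(optimize.brentq(f, 1e-8, 0.999999 * _d_upper(design, n, alpha)))


def _d_upper(design: Design, n: int, alpha: float) -> float:
    # effect size at which two-sided power is essentially 1; safe bracket end
    d = 1.0
    while nhst_power(design, n, d, alpha) < 0.999999:
        d *= 2.0
        if d > 1e6:
            break
    return d


def small_telescopes_bound(
    n_orig_per_group: int, alpha: float = 0.05, power_level: float = 1.0 / 3.0
) -> float:
    """Small-telescopes equivalence bound for a replication study.

    The Cohen's d at which a two-sided, two-group t test with the original
    study's per-group n has exactly ``power_level`` power (33% by default).
    A replication that rejects this d argues the original study could not
    have reliably detected its own effect.
    """
    check_alpha(alpha)
    if n_orig_per_group < 3:
        raise ValueError(f"original per-group n must be >= 3, got {n_orig_per_group}")
    if not alpha < power_level < 1.0:
        raise ValueError(f"power level must lie in (alpha, 1), got {power_level}")
    f = lambda d: nhst_power(Design.independent, n_orig_per_group, d, alpha) - power_level
    return float(
        optimize.brentq(f, 1e-8, 0.999999 * _d_upper(Design.independent, n_orig_per_group, alpha))
    )


_BENCHMARKS = {
    "d": {"small": 0.2, "medium": 0.5, "large": 0.8},
    "r": {"small": 0.1, "medium": 0.3, "large": 0.5},
    # d benchmarks scaled by 1/sqrt(2) (the d to d_z ratio at r = .5),
    # rounded to two decimals: .14, .35, .57
    "dz": {s: round(b / math.sqrt(2.0), 2) for s, b in
           {"small": 0.2, "medium": 0.5, "large": 0.8}.items()},
}

_BENCH_SCALE = {
    "d": BoundScale.cohen_d,
    "dz": BoundScale.cohen_dz,
    "r": BoundScale.correlation,
}


def benchmark_bounds(metric: str, size: str) -> Bounds:
    """Symmetric bounds at the conventional small/medium/large benchmarks.

    Cohen's d: .2/.5/.8; r: .1/.3/.5; d_z: the d benchmarks divided by
    sqrt(2) and rounded to two decimals (.14/.35/.57).
    """
    try:
        mag = _BENCHMARKS[metric][size]
    except KeyError:
        raise ValueError(
            f"unknown benchmark metric/size '{metric}'/'{size}'; "
            f"metrics: {sorted(_BENCHMARKS)}, sizes: small/medium/large"
        ) from None
    return Bounds.symmetric(mag, scale=_BENCH_SCALE[metric])
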