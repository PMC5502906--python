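# Methods

## The TOST procedure

For a chosen pair of signed equivalence bounds Δ_L < 0 < Δ_U (asymmetric
bounds are allowed; one bound may be infinite for inferiority/superiority
testing), the two one-sided tests procedure tests

- H0₁: Δ ≤ Δ_L against the upper tail, and
- H0₂: Δ ≥ Δ_U against the lower tail,

where Δ is the effect of interest. With an estimate `est` and standard
error `SE`, the statistics are

```
stat_low  = (est − Δ_L) / SE        stat_high = (est − Δ_U) / SE
```

and equivalence is declared at level α when `stat_low ≥ t(df, 1−α)` **and**
`stat_high ≤ −t(df, 1−α)`, i.e. when both one-sided p values are below α.
The reported headline p is the larger of the two (if it rejects, both do).
Bounds are always stored **signed** and the signed bound is subtracted; this
single convention is applied uniformly across all five designs, which is the
only reading consistent with TOST logic (the lower-bound statistic must be
significantly *positive*, the upper-bound statistic significantly
*negative*).

Per design:

| design       | est             | SE                                   | df        |
|--------------|-----------------|--------------------------------------|-----------|
| independent (Student) | M₁ − M₂ | σ_p √(1/n₁ + 1/n₂)                  | n₁+n₂−2   |
| independent (Welch)   | M₁ − M₂ | √(SD₁²/n₁ + SD₂²/n₂)                | Welch–Satterthwaite |
| paired       | M₁ − M₂         | SD_diff/√n, SD_diff = √(SD₁²+SD₂²−2r·SD₁SD₂) | n−1 |
| one-sample   | M − μ           | SD/√n                                | n−1       |
| correlation  | z(r) = atanh r  | 1/√(n−3)                             | — (normal) |
| meta-analytic| pooled d or g   | meta-analytic SE (given)             | — (normal) |

σ_p is the pooled SD, `√(((n₁−1)SD₁² + (n₂−1)SD₂²)/(n₁+n₂−2))`. Welch is
the default test variant (group sizes are rarely equal in practice); the
Welch df is carried as a real number and never rounded.

Standardized bounds are converted to raw units before testing: Cohen's d
bounds via σ_p for two-group designs (also under Welch — the bound's meaning
should not depend on the variance assumption), via the sample SD for
one-sample designs, and Cohen's d_z bounds via SD_diff for paired designs.
Correlation bounds are transformed with Fisher's z alongside the estimate.

With one infinite bound the statistic on that side is ±∞ with one-sided
p = 0 by convention; the headline p is taken over the finite side only, so
the procedure degrades gracefully into a single one-sided test.

## Intervals and the four-outcome classification

Equivalence at level α is dual to the (1 − 2α) two-sided CI falling
*strictly inside* (Δ_L, Δ_U): an endpoint exactly on a bound corresponds to
p = α, which does not reject (rejection requires p < α), so the comparison
is open. The ordinary test against zero uses the (1 − α) CI. Crossing the
two binary outcomes gives four categories: equivalent only, different from
zero only, both (a significant but practically negligible effect), or
undetermined. At α = .05 these are the familiar 90%/95% interval pair.
Correlation CIs are computed on the z scale and back-transformed; since the
transform is strictly monotone, the duality carries over to the r scale.

## Power analysis

**Approximation.** Under a true effect of zero, the per-group sample size
for an independent-groups equivalence test with standardized bound Δ is

```
n = ⌈ 2 (z_α + z_{β/2})² / Δ² ⌉
```

evaluated per bound (the larger requirement wins for asymmetric bounds).
z_{β/2} is the upper-tail normal quantile at β/2 — e.g. β = .2 gives
z₀.₁₀ = 1.2816. Paired and one-sample designs need half that count (in
pairs/observations) with Δ read as d_z / d. For correlations the bound is
first converted to Cohen's d (d = 2r/√(1−r²), the point-biserial
convention used by G*Power); since that model has noncentrality d·√N/2 on
the *total* N, the approximate total is 4(z_α + z_{β/2})²/d².

**Exact.** The probability that both one-sided tests reject is computed as

```
power = max(0, F_nt(−t_crit; df, ncp_U) − F_nt(t_crit; df, ncp_L))
```

with `t_crit = t(df, 1−α)` and `ncp_X = (true_effect − Δ_X)/se_unit`,
`se_unit = √(2/n)` per independent group or `√(1/n)` for paired/one-sample.
This difference-of-CDFs form ignores the (positive) dependence of the two
statistics through the shared SE estimate; it is standard practice, exact
enough that the bracketed-bisection sample-size search lands on the
analytically verified anchors (n = 70 at Δ = ±.5, α = .05, 80% power;
n = 128 at 90%, α = .01), and a documented extension point (Owen's Q
integration would remove the approximation). A consequence worth knowing:
cells whose power sits within ~2·10⁻⁴ of the target can flip by one
observation relative to other implementations. Correlation power is
computed on the Fisher-z scale against the normal, matching the test
actually performed; the r→d route is used only for the quick approximation.

The search (`n_exact`) doubles an upper bracket until power exceeds the
target, then bisects on the integer n; the result satisfies
`power(n) ≥ target > power(n−1)`. Sample sizes are always rounded up, and a
hard cap of 10⁷ guards against bounds that straddle the true effect too
tightly for the requested power ever to be reached.

**NHST cross-anchors.** `nhst_n` and the `nhst` mode of `min_detectable`
use the same noncentral-t machinery for ordinary two-sided tests
(ncp = d√(n/2) two-group, d√n paired/one-sample). These reproduce the
standard results n = 176 per group for d = .3 at 80%/α = .05 and d_z = .212
for 176 pairs. Note that a common software sensitivity value of 0.389 for
n = 100/group does not agree with the exact noncentral-t computation, which
gives 0.398; this package reports the computed value.

## Setting equivalence bounds

- **Resource-based SESOI** (`min_detectable`, mode `equivalence`): invert
  the approximation at your maximum affordable n —
  Δ = √2(z_α + z_{β/2})/√n per independent group (drop the √2 for
  paired/one-sample). With 100 per group, α = .05 and 80% power this gives
  Δ = 0.414: the smallest bound your resources let you reject reliably.
- **Small telescopes** (`small_telescopes_bound`): for replications, set
  Δ_U to the d at which the *original* study's design had 33% power
  (root-finding on the two-sided noncentral-t power curve). An original
  study with 30 per group gives d ≈ 0.40.
- **Benchmarks** (`benchmark_bounds`): d ∈ {.2, .5, .8}, r ∈ {.1, .3, .5};
  d_z benchmarks are the d benchmarks divided by √2 — the d-to-d_z ratio at
  r = .5 — rounded to two decimals: {.14, .35, .57}.

## Monte Carlo validation

The `simulate` module draws normal data at specified population parameters
and runs the package's own tests on the per-replication summary statistics.
True effects are standardized: Cohen's d with standardizer √((σ₁²+σ₂²)/2)
for independent groups, d_z (standardizer the population SD of difference
scores, with pair correlation r) for paired data, d for one-sample, and the
population correlation ρ for the correlation design. Seeding is
counter-based — replication i draws from `default_rng([seed, i])` — so any
replication's data are reproducible independently of execution order or the
number of replications requested.

What the generator emulates: sampling variability of means, SDs and
correlations under exact normality, which is precisely the model the tests
assume. What it does not: skewness, heavy tails, outliers, measurement
error, unequal variances combined with standardized bounds, or selection
effects. Passing validation therefore certifies the *internal* consistency
of the analytic machinery (rejection rates match the noncentral-t power
function to Monte Carlo error; the rate at a boundary-true effect sits at
α), not robustness of the t tests to assumption violations on real data.

Validation sizes used by the test suite: 20,000 replications for size
control and for each cell of a 12-condition grid crossing the three mean
designs with several (n, Δ, true effect) combinations; 1,000 randomized
inputs per design for the CI/TOST duality check; 300 randomized datasets
per design for agreement with ordinary-t oracles on bound-shifted raw data.
At 20,000 replications the binomial SE near 80% power is ≈0.0028, and
checks use a 3-SE band.

## Numerical choices and degenerate inputs

- Distribution primitives come from scipy (`stdtr`/`stdtrit`/`ndtr` for the
  central t and normal, `nct` for noncentral t). The noncentral-t CDF can
  underflow to NaN deep in a tail; those values are resolved to 0/1 by the
  side of the noncentrality parameter.
- All statistics and p values are carried at full double precision;
  rounding (2 decimals for statistics, 3 for p values with a "< .001"
  floor) happens only in the CLI display layer. JSON output keeps full
  precision and round-trips, including infinite bounds.
- Validation rejects n < 2 (n < 4 for correlations, where the Fisher
  variance 1/(n−3) needs headroom), non-positive SDs and SEs, |r| ≥ 1,
  inverted bounds, and two infinite bounds. A CI endpoint exactly equal to
  a bound is classified as *not* equivalent (ties break against rejection).
- `validate` is idempotent; models are immutable after construction.

## Limitations

- Summary statistics are the unit of input; raw-data ingestion exists only
  inside the simulation module.
- No Hedges-style small-sample correction is applied when converting
  standardized bounds, and no unequal-variance standardizer (e.g. Glass's
  Δ) is offered.
- Power for the meta-analytic test is not provided (its SE is an input, not
  a design quantity), and the exact power function treats the two one-sided
  tests as perfectly dependent through their means only (difference-of-CDFs
  form, above).
- The four-outcome classification and ASCII interval rendering are textual;
  no graphical output is produced.
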