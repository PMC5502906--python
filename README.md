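# tosteq

Equivalence testing with the two one-sided tests (TOST) procedure, from
summary statistics.

A nonsignificant p value cannot show that an effect is absent — the study may
simply have been underpowered. What *can* be done in a frequentist framework
is to reject all effects large enough to matter: pick a smallest effect size
of interest (SESOI), turn it into lower and upper equivalence bounds
(Δ_L, Δ_U), and test the two composite null hypotheses H0₁: Δ ≤ Δ_L and
H0₂: Δ ≥ Δ_U with one one-sided test each. If both reject at level α, the
true effect lies inside (Δ_L, Δ_U) and is practically equivalent to zero.
Equivalently, the (1 − 2α) confidence interval — 90% at α = .05 — falls
strictly inside the bounds.

`tosteq` is aimed at researchers (psychology, biostatistics, meta-science)
who work from reported summary statistics rather than raw data. It provides:

- **TOST equivalence tests** for independent means (Student and Welch),
  paired means, one-sample means, correlations (Fisher-z), and
  meta-analytic effect sizes — with bounds given in raw units or as
  standardized effect sizes (Cohen's *d*, *d_z*, or *r*).
- **Power analysis**: the normal-approximation sample-size formula
  n = 2(z_α + z_{β/2})²/Δ² per group, and an exact path via the noncentral-t
  distribution that also handles nonzero true effects.
- **Bound-setting helpers**: resource-based SESOI (the effect your maximum n
  can resolve), the small-telescopes rule (the effect an original study had
  33% power to detect), and conventional small/medium/large benchmarks.
- **Monte Carlo validation**: a simulation module that draws synthetic
  normal/bivariate-normal data and verifies that empirical rejection rates
  match the analytic power functions and that error rates are controlled at
  α when the true effect sits on a bound.

## Worked example

A replication study compared moral judgments after exposure to organic food
(control: n = 95, M = 5.25, SD = .95; organic: n = 89, M = 5.22, SD = .83).
The original study had n = 21 per group, so the small-telescopes rule sets
the equivalence bound near d = .48, about 0.384 scale points at the pooled
SD of .894:

```sh
tosteq ttest --design independent --m1 5.25 --sd1 .95 --n1 95 \
             --m2 5.22 --sd2 .83 --n2 89 \
             --low -0.384 --high 0.384 --scale raw --alpha .05 --var-equal
```

prints

```
Equivalence test (TOST), independent means, Student
  t_L (182) = 3.14, p < .001
  t_U (182) = -2.68, p = .004
  TOST p = .004 -> statistically equivalent at alpha = 0.05
  90% CI [-0.188, 0.248]; 95% CI [-0.230, 0.290]
  bounds (raw): [-0.384, 0.384]
  outcome: equivalent_only
               --==============#==============---
     L                        0                       U
```

Both one-sided tests reject (the headline TOST p is the larger of the two,
here .004), so effects larger than ±0.384 scale points can be rejected: the
replication is statistically equivalent to zero at these bounds. The 90% CI
sits inside the bounds — the interval view of the same decision — and the
95% CI covers zero, so the joint outcome is "equivalent only".

The same analysis from Python:

```python
from tosteq import Bounds, GroupSummary, tost_independent

res = tost_independent(
    GroupSummary(n=95, mean=5.25, sd=0.95),
    GroupSummary(n=89, mean=5.22, sd=0.83),
    Bounds(low=-0.384, high=0.384),
    alpha=0.05, var_equal=True,
)
res.stat_low, res.stat_high, res.p_tost, res.equivalent
# (3.1392, -2.6842, 0.00397, True)
```

Other subcommands: `corr` (Fisher-z correlation TOST), `meta`
(meta-analytic effect), `power` (required n or achieved power), `bounds`
(`benchmark` / `sesoi` / `telescopes`), and `simulate` (Monte Carlo
rejection rates). Every subcommand takes `--json` for machine-readable
output and `ttest`/`power` accept `--batch file.csv` for row-per-analysis
processing. For example:

```sh
$ tosteq power --design independent --bound 0.5 --method approximation
Required sample size (approximation): 69 per group
  achieved exact power at that n: 0.7985

$ tosteq bounds sesoi --n 100
SESOI (equivalence, independent, n=100, 80% power): 0.414
```

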