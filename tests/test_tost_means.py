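import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tosteq import (
    Bounds,
    BoundScale,
    GroupSummary,
    OneSampleSummary,
    PairedSummary,
    convert_bounds,
    pooled_sd,
    tost_independent,
    tost_one_sample,
    tost_paired,
    welch_df,
)


class TestPooledSD:
    def test_worked_example(self, organic_replication):
        g1, g2, _ = organic_replication
        assert pooled_sd(g1, g2) == pytest.approx(0.894, abs=5e-4)

    def test_equal_sds_pool_to_themselves(self):
        g = GroupSummary(n=10, mean=0.0, sd=2.0)
        assert pooled_sd(g, g) == pytest.approx(2.0, rel=1e-12)

    def test_hand_calculator_case(self):
        # ((3-1)*1 + (5-1)*9) / (3+5-2) = 38/6
        g1 = GroupSummary(n=3, mean=0.0, sd=1.0)
        g2 = GroupSummary(n=5, mean=0.0, sd=3.0)
        assert pooled_sd(g1, g2) == pytest.approx(math.sqrt(38 / 6), rel=1e-12)


class TestWelchDf:
    def test_balanced_equal_variance_gives_student_df(self):
        g = GroupSummary(n=10, mean=0.0, sd=1.0)
        assert welch_df(g, g) == pytest.approx(18.0, rel=1e-12)

    def test_hand_calculator_case(self):
        # v1 = 1/10, v2 = 9/20; (v1+v2)^2 / (v1^2/9 + v2^2/19)
        g1 = GroupSummary(n=10, mean=0.0, sd=1.0)
        g2 = GroupSummary(n=20, mean=0.0, sd=3.0)
        v1, v2 = 0.1, 0.45
        expected = (v1 + v2) ** 2 / (v1**2 / 9 + v2**2 / 19)
        assert welch_df(g1, g2) == pytest.approx(expected, rel=1e-12)

    @given(
        n1=st.integers(2, 500),
        n2=st.integers(2, 500),
        sd1=st.floats(0.1, 10),
        sd2=st.floats(0.1, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_satterthwaite_df_bracketing(self, n1, n2, sd1, sd2):
        g1 = GroupSummary(n=n1, mean=0.0, sd=sd1)
        g2 = GroupSummary(n=n2, mean=0.0, sd=sd2)
        df = welch_df(g1, g2)
        assert min(n1, n2) - 1 <= df + 1e-9
        assert df <= n1 + n2 - 2 + 1e-9


class TestIndependent:
    def test_worked_example_statistics(self, organic_replication):
        g1, g2, bounds = organic_replication
        res = tost_independent(g1, g2, bounds, alpha=0.05, var_equal=True)
        assert res.stat_low == pytest.approx(3.14, abs=0.01)
        assert res.stat_high == pytest.approx(-2.69, abs=0.01)
        assert res.df == 182
        assert res.p_low == pytest.approx(0.001, abs=5e-4)
        assert res.p_high == pytest.approx(0.004, abs=5e-4)
        assert res.p_tost == res.p_high
        assert res.equivalent

    def test_equal_means_symmetric_bounds_mirror(self):
        g1 = GroupSummary(n=40, mean=1.0, sd=1.1)
        g2 = GroupSummary(n=35, mean=1.0, sd=0.9)
        res = tost_independent(g1, g2, Bounds.symmetric(0.4))
        assert res.stat_low == pytest.approx(-res.stat_high, rel=1e-12)
        assert res.p_low == pytest.approx(res.p_high, rel=1e-9)

    def test_welch_statistics_match_student_at_balance(self):
        g1 = GroupSummary(n=25, mean=0.4, sd=1.3)
        g2 = GroupSummary(n=25, mean=0.1, sd=1.3)
        b = Bounds.symmetric(0.5)
        student = tost_independent(g1, g2, b, var_equal=True)
        welch = tost_independent(g1, g2, b, var_equal=False)
        assert welch.stat_low == pytest.approx(student.stat_low, rel=1e-12)
        assert welch.stat_high == pytest.approx(student.stat_high, rel=1e-12)
        assert welch.df == pytest.approx(48.0)

    @pytest.mark.parametrize("var_equal", [True, False])
    def test_one_sided_p_matches_shifted_t_test_oracle(self, rng, var_equal):
        """Each TOST p equals the p of an ordinary one-sided t test on data
        whose second group is shifted by the corresponding bound."""
        for _ in range(25):
            x1 = rng.normal(0.2, 1.0, rng.integers(5, 60))
            x2 = rng.normal(0.0, 1.4, rng.integers(5, 60))
            low, high = -0.6, 0.45
            g1 = GroupSummary(n=len(x1), mean=x1.mean(), sd=x1.std(ddof=1))
            g2 = GroupSummary(n=len(x2), mean=x2.mean(), sd=x2.std(ddof=1))
            res = tost_independent(g1, g2, Bounds(low=low, high=high), var_equal=var_equal)
            p_lo = stats.ttest_ind(x1, x2 + low, equal_var=var_equal,
                                   alternative="greater").pvalue
            p_hi = stats.ttest_ind(x1, x2 + high, equal_var=var_equal,
                                   alternative="less").pvalue
            assert res.p_low == pytest.approx(p_lo, rel=1e-9)
            assert res.p_high == pytest.approx(p_hi, rel=1e-9)

    def test_cohen_d_bounds_use_pooled_sd_for_both_variants(self, organic_replication):
        g1, g2, _ = organic_replication
        d_bounds = Bounds.symmetric(0.48, scale=BoundScale.cohen_d)
        raw = 0.48 * pooled_sd(g1, g2)
        for var_equal in (True, False):
            res = tost_independent(g1, g2, d_bounds, var_equal=var_equal)
            assert res.bounds_raw.high == pytest.approx(raw, rel=1e-12)
            assert res.bounds_raw.scale is BoundScale.raw

    def test_inferiority_single_bound(self, organic_replication):
        g1, g2, _ = organic_replication
        res = tost_independent(
            g1, g2, Bounds(low=-math.inf, high=0.384), var_equal=True
        )
        assert res.stat_low == math.inf
        assert res.p_low == 0.0
        assert res.p_tost == res.p_high  # infinite-bound side excluded
        assert res.equivalent

    @given(
        m1=st.floats(-3, 3),
        m2=st.floats(-3, 3),
        low=st.floats(-2.0, -0.05),
        high=st.floats(0.05, 2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_negation_symmetry(self, m1, m2, low, high):
        """Negating all means and mirroring the bounds negates the statistics
        and swaps the one-sided p values."""
        g1 = GroupSummary(n=30, mean=m1, sd=1.2)
        g2 = GroupSummary(n=25, mean=m2, sd=0.8)
        n1 = GroupSummary(n=30, mean=-m1, sd=1.2)
        n2 = GroupSummary(n=25, mean=-m2, sd=0.8)
        res = tost_independent(g1, g2, Bounds(low=low, high=high))
        neg = tost_independent(n1, n2, Bounds(low=-high, high=-low))
        assert neg.stat_low == pytest.approx(-res.stat_high, rel=1e-9, abs=1e-12)
        assert neg.stat_high == pytest.approx(-res.stat_low, rel=1e-9, abs=1e-12)
        assert neg.p_low == pytest.approx(res.p_high, rel=1e-7, abs=1e-12)
        assert neg.p_high == pytest.approx(res.p_low, rel=1e-7, abs=1e-12)


class TestPaired:
    def test_unit_sds_r_half_gives_unit_sd_diff(self):
        p = PairedSummary(n_pairs=30, mean1=0.2, mean2=0.0, sd1=1.0, sd2=1.0, r=0.5)
        assert p.sd_diff == pytest.approx(1.0, rel=1e-12)
        raw = tost_paired(p, Bounds.symmetric(0.4, scale=BoundScale.raw))
        dz = tost_paired(p, Bounds.symmetric(0.4, scale=BoundScale.cohen_dz))
        assert raw.stat_low == pytest.approx(dz.stat_low, rel=1e-12)

    def test_equal_means_symmetry(self):
        p = PairedSummary(n_pairs=25, mean1=1.0, mean2=1.0, sd1=1.4, sd2=1.0, r=0.3)
        res = tost_paired(p, Bounds.symmetric(0.5))
        assert res.p_low == pytest.approx(res.p_high, rel=1e-9)

    def test_reduces_to_one_sample_t_on_differences(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 50))
            z1 = rng.standard_normal(n)
            z2 = rng.standard_normal(n)
            x1 = 0.1 + 1.2 * z1
            x2 = 0.9 * (0.6 * z1 + math.sqrt(1 - 0.36) * z2)
            p = PairedSummary(
                n_pairs=n, mean1=x1.mean(), mean2=x2.mean(),
                sd1=x1.std(ddof=1), sd2=x2.std(ddof=1),
                r=float(np.corrcoef(x1, x2)[0, 1]),
            )
            low, high = -0.5, 0.5
            res = tost_paired(p, Bounds(low=low, high=high))
            d = x1 - x2
            p_lo = stats.ttest_1samp(d - low, 0.0, alternative="greater").pvalue
            p_hi = stats.ttest_1samp(d - high, 0.0, alternative="less").pvalue
            assert res.p_low == pytest.approx(p_lo, rel=1e-9)
            assert res.p_high == pytest.approx(p_hi, rel=1e-9)


class TestOneSample:
    def test_mean_at_reference_mirrors(self):
        s = OneSampleSummary(n=20, mean=3.0, sd=1.0, mu=3.0)
        res = tost_one_sample(s, Bounds.symmetric(0.5))
        assert res.stat_low == pytest.approx(-res.stat_high, rel=1e-12)

    def test_statistic_at_the_null_boundary(self):
        s = OneSampleSummary(n=20, mean=3.5, sd=1.0, mu=3.0)
        res = tost_one_sample(s, Bounds(low=-0.5, high=0.5))
        assert res.stat_high == pytest.approx(0.0, abs=1e-12)
        assert res.p_high == pytest.approx(0.5, rel=1e-12)

    def test_matches_shifted_one_sample_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(0.3, 1.1, int(rng.integers(5, 60)))
            s = OneSampleSummary(n=len(x), mean=x.mean(), sd=x.std(ddof=1), mu=0.1)
            low, high = -0.4, 0.6
            res = tost_one_sample(s, Bounds(low=low, high=high))
            p_lo = stats.ttest_1samp(x, 0.1 + low, alternative="greater").pvalue
            p_hi = stats.ttest_1samp(x, 0.1 + high, alternative="less").pvalue
            assert res.p_low == pytest.approx(p_lo, rel=1e-9)
            assert res.p_high == pytest.approx(p_hi, rel=1e-9)


class TestConvertBounds:
    def test_to_raw_multiplies(self):
        b = convert_bounds(Bounds.symmetric(0.5, scale=BoundScale.cohen_d), 2.0, "to_raw")
        assert (b.low, b.high) == (-1.0, 1.0)
        assert b.scale is BoundScale.raw

    def test_round_trip_is_identity(self):
        b0 = Bounds(low=-0.2, high=0.4, scale=BoundScale.cohen_d)
        back = convert_bounds(convert_bounds(b0, 1.7, "to_raw"), 1.7, "to_standardized")
        assert back.low == pytest.approx(b0.low, rel=1e-12)
        assert back.high == pytest.approx(b0.high, rel=1e-12)
        assert back.scale is BoundScale.cohen_d

    def test_standardized_to_raw_follows_the_formula(self):
        # d = .48 with sigma = .894 gives .429 on the raw scale
        b = convert_bounds(Bounds.symmetric(0.48, scale=BoundScale.cohen_d), 0.894, "to_raw")
        assert b.high == pytest.approx(0.429, abs=1e-3)

    def test_infinite_endpoints_preserved(self):
        b = convert_bounds(Bounds(low=-math.inf, high=0.5, scale=BoundScale.cohen_d),
                           2.0, "to_raw")
        assert b.low == -math.inf
        assert b.high == pytest.approx(1.0)

    def test_nonpositive_standardizer_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            convert_bounds(Bounds.symmetric(0.5), 0.0, "to_raw")


def test_p_tost_is_the_larger_one_sided_p(rng):
    for _ in range(50):
        g1 = GroupSummary(n=int(rng.integers(5, 80)), mean=rng.normal(), sd=rng.uniform(0.5, 2))
        g2 = GroupSummary(n=int(rng.integers(5, 80)), mean=rng.normal(), sd=rng.uniform(0.5, 2))
        res = tost_independent(g1, g2, Bounds.symmetric(0.5))
        assert res.p_tost == max(res.p_low, res.p_high)
        assert res.equivalent == (res.p_low < 0.05 and res.p_high < 0.05)
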