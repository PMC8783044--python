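"""Cohort statistics: VI, proportion CIs, Welch t, Mann-Whitney U, F-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from acquant.stats import (
    induction_index,
    mann_whitney_u,
    proportion_ci,
    star_code,
    summarize_groups,
    variance_f_test,
    welch_t,
)


class TestInductionIndex:
    def test_wild_type_cohort_gives_three(self):
        assert induction_index([3] * 44) == 3.0

    def test_uninduced_cohort_gives_zero(self):
        assert induction_index([0] * 10) == 0.0

    def test_two_animal_mean(self):
        assert induction_index([3, 2]) == 2.5

    def test_dataframe_input(self):
        df = pd.DataFrame({"animal_id": [1, 2], "induced_vpcs": [3, 4]})
        assert induction_index(df) == 3.5

    def test_invariant_under_reordering(self, rng):
        counts = rng.integers(0, 7, size=30)
        assert induction_index(counts) == induction_index(counts[::-1])

    def test_rejections(self):
        with pytest.raises(ValueError, match="empty"):
            induction_index([])
        with pytest.raises(ValueError, match=r"\[0, 6\]"):
            induction_index([3, 7])


def wilson_reference(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval, written out independently."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestProportionCI:
    def test_matches_closed_form_wilson(self):
        p, lo, hi = proportion_ci(12, 16)
        ref_lo, ref_hi = wilson_reference(12, 16)
        assert p == pytest.approx(0.75)
        assert lo == pytest.approx(ref_lo, abs=1e-6)
        assert hi == pytest.approx(ref_hi, abs=1e-6)

    def test_boundaries(self):
        p, lo, hi = proportion_ci(5, 5)
        assert p == 1.0 and hi == pytest.approx(1.0)
        p, lo, hi = proportion_ci(0, 8)
        assert p == 0.0 and lo == pytest.approx(0.0)

    @given(st.integers(1, 200), st.floats(0.05, 0.95))
    def test_interval_contains_estimate_and_shrinks_with_n(self, n, frac):
        k = int(round(frac * n))
        p, lo, hi = proportion_ci(k, n)
        assert lo <= p <= hi
        p4, lo4, hi4 = proportion_ci(4 * k, 4 * n)
        assert (hi4 - lo4) <= (hi - lo) + 1e-12

    def test_clopper_pearson_available(self):
        _, lo, hi = proportion_ci(3, 10, method="clopper-pearson")
        assert 0 < lo < 0.3 < hi < 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 4)


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        # x=(1,2,3), y=(4,5,6): s^2 = 1 each, se = sqrt(2/3),
        # t = -3/se, df = (2/3)^2 / (2 * (1/3)^2 / 2) = 4
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        se = np.sqrt(2 / 3)
        assert t == pytest.approx(-3 / se)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(2 * sps.t(4).cdf(-3 / se))

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t([1.0], [1, 2, 3])

    def test_degenerate_zero_variance_equal_means_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            welch_t([2.0, 2.0], [2.0, 2.0])


class TestMannWhitney:
    def test_extreme_small_sample_exact_p(self):
        # all x below all y: U = 0; 2/6 of rank arrangements are as extreme
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_approximate_p_is_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_extreme_ordering_minimal_u(self):
        u, _ = mann_whitney_u([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert u == 0.0

    def test_large_samples_use_tie_corrected_approximation(self, rng):
        x = rng.integers(0, 4, size=30)  # heavy ties
        y = rng.integers(1, 5, size=35)
        u, p = mann_whitney_u(x, y)
        assert 0.0 <= p <= 1.0
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue), abs=5e-3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestVarianceF:
    def test_equal_variances_give_unity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        f, p = variance_f_test(x, [10 + v for v in x])
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_reciprocal_symmetry(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(scale=2.0, size=15)
        fxy, pxy = variance_f_test(x, y)
        fyx, pyx = variance_f_test(y, x)
        assert fxy == pytest.approx(1 / fyx)
        assert pxy == pytest.approx(pyx)

    def test_reported_delta_spread_ratio(self, rng):
        # cohort spreads s.d. 2.380 (n=134) vs 1.584 (n=113):
        # F = (2.380 / 1.584)^2 ~= 2.258
        def scaled(n, sd):
            v = rng.normal(size=n)
            return (v - v.mean()) / v.std(ddof=1) * sd

        f, p = variance_f_test(scaled(134, 2.380), scaled(113, 1.584))
        assert f == pytest.approx((2.380 / 1.584) ** 2, abs=1e-9)
        assert p < 0.0001

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            variance_f_test([1.0, 2.0], [3.0, 3.0])


class TestSummaries:
    def test_star_codes(self):
        assert star_code(0.03) == "*"
        assert star_code(0.005) == "**"
        assert star_code(0.0005) == "***"
        assert star_code(0.00005) == "****"
        assert star_code(0.2) == "ns"

    def make_table(self, rng):
        return pd.DataFrame(
            {
                "genotype": ["ctrl"] * 10 + ["mut"] * 12,
                "r_a": np.concatenate(
                    [rng.normal(0.46, 0.03, 10), rng.normal(0.43, 0.05, 12)]
                ),
            }
        )

    def test_report_rederivable_by_recount(self, rng):
        table = self.make_table(rng)
        report = summarize_groups(table, "r_a", test="welch")
        g = report["groups"].set_index("genotype")
        for name in ("ctrl", "mut"):
            v = table.loc[table.genotype == name, "r_a"]
            assert g.loc[name, "n"] == len(v)
            assert g.loc[name, "mean"] == pytest.approx(v.mean())
            assert g.loc[name, "sd"] == pytest.approx(v.std(ddof=1))
            assert g.loc[name, "median"] == pytest.approx(v.median())
        t = report["tests"][0]
        stat, df, p = welch_t(
            table.loc[table.genotype == "ctrl", "r_a"], table.loc[table.genotype == "mut", "r_a"]
        )
        assert t["statistic"] == pytest.approx(stat)
        assert t["p"] == pytest.approx(p)

    def test_single_value_group_flagged(self, rng, caplog):
        table = pd.DataFrame({"genotype": ["a", "b", "b"], "m": [1.0, 2.0, 3.0]})
        report = summarize_groups(table, "m", test="mwu")
        g = report["groups"].set_index("genotype")
        assert np.isnan(g.loc["a", "sd"])
        assert any("single observation" in r.message for r in caplog.records)

    def test_unknown_metric_or_test_rejected(self, rng):
        table = self.make_table(rng)
        with pytest.raises(ValueError, match="metric"):
            summarize_groups(table, "nope")
        with pytest.raises(ValueError, match="test"):
            summarize_groups(table, "r_a", test="anova")
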