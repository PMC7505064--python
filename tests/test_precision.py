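import numpy as np
import pandas as pd
import pytest

from bearcondition import (
    PrecisionSummary,
    coefficient_of_variation,
    cv_equality_test,
    min_measurements,
    one_way_anova_tukey,
    pearson_correlation,
    se_at_n,
    two_way_anova,
)

# Published within-photo replicate statistics (mean, SD) per ratio method.
REPLICATE_TABLE = {
    "TH:HBL": (0.4316, 0.0016),
    "TH:EBL": (0.4266, 0.0015),
    "TH:PBL": (0.4163, 0.0015),
    "TH:HTL": (0.7504, 0.0040),
}


class TestCv:
    def test_constant_series_is_zero(self):
        assert coefficient_of_variation([0.75] * 10) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_replicate_series_cv(self):
        mean, sd = REPLICATE_TABLE["TH:HTL"]
        assert round(100.0 * sd / mean, 2) == 0.53
        # a reconstructed two-point series with that mean and SD
        series = [mean - sd / np.sqrt(2), mean + sd / np.sqrt(2)]
        assert coefficient_of_variation(series) == \
            pytest.approx(100.0 * sd / mean, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-2.0, 0.0, 2.0])


class TestSeAtN:
    @pytest.mark.parametrize("n,expected", [(2, 0.0028), (3, 0.0023),
                                            (4, 0.0020)])
    def test_published_se_columns(self, n, expected):
        assert round(se_at_n(0.0040, n), 4) == expected

    def test_n_one_returns_sd(self):
        assert se_at_n(0.0123, 1) == 0.0123

    def test_identity_with_sqrt_n(self):
        for n in (1, 2, 3, 4, 10, 50):
            assert se_at_n(0.004, n) * np.sqrt(n) == pytest.approx(0.004)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            se_at_n(0.004, 0)


class TestMinMeasurements:
    def test_published_rule_three_replicates(self):
        """The worst method (SD 0.0040) dictates measuring 3 times."""
        counts = [min_measurements(sd) for _, sd in REPLICATE_TABLE.values()]
        assert max(counts) == 3

    def test_enumeration_oracle(self):
        # smallest n with 0.005/sqrt(n) < 0.0025 found by enumeration
        n = 1
        while not 0.005 / np.sqrt(n) < 0.0025:
            n += 1
        assert n == 5
        assert min_measurements(0.005) == 5

    def test_zero_sd(self):
        assert min_measurements(0.0) == 1

    def test_monotonicity(self):
        sds = np.linspace(0.0, 0.02, 40)
        counts = [min_measurements(s) for s in sds]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        thresholds = np.linspace(0.001, 0.01, 40)
        by_thr = [min_measurements(0.004, t) for t in thresholds]
        assert all(a >= b for a, b in zip(by_thr, by_thr[1:]))


class TestCvEquality:
    def test_equal_cvs_give_zero(self):
        res = cv_equality_test([2.5, 2.5, 2.5], [10, 20, 30])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_two_group_literature_formula(self):
        """Frozen value from the weighted chi-square formula computed by hand:
        c = (9*0.10 + 11*0.15)/20 = 0.1275,
        D = (9*0.0275^2 + 11*0.0225^2) / (0.1275^2 * (0.5 + 0.1275^2))."""
        res = cv_equality_test([0.10, 0.15], [10, 12])
        num = 9 * 0.0275**2 + 11 * 0.0225**2
        den = 0.1275**2 * (0.5 + 0.1275**2)
        assert res.statistic == pytest.approx(num / den, rel=1e-12)
        assert res.statistic == pytest.approx(1.47453, abs=1e-4)
        assert res.df == 1

    def test_percent_fraction_invariance(self):
        as_pct = cv_equality_test([2.47, 2.19, 3.18, 3.93], [15, 15, 25, 34])
        as_frac = cv_equality_test([0.0247, 0.0219, 0.0318, 0.0393],
                                   [15, 15, 25, 34])
        assert as_pct.statistic == pytest.approx(as_frac.statistic, rel=1e-12)
        # the published four-method comparison is non-significant
        assert as_pct.p_value > 0.05

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cv_equality_test([2.5], [10])
        with pytest.raises(ValueError):
            cv_equality_test([2.5, -1.0], [10, 10])
        with pytest.raises(ValueError):
            cv_equality_test([2.5, 2.0], [10, 1])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOneWayAnova:
    def test_identical_groups(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = one_way_anova_tukey(g)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        for _, row in res.tukey.iterrows():
            assert row["p_adj"] > 0.9

    def test_large_shift_detected_against_t_test_oracle(self, rng):
        from scipy import stats

        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(5.0, 1.0, 10)
        res = one_way_anova_tukey({"a": a, "b": b})
        assert res.p_value < 0.001
        # with two groups the ANOVA F equals the pooled t squared
        t, p_t = stats.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t**2, rel=1e-9)
        assert res.p_value == pytest.approx(p_t, rel=1e-6)

    def test_unbalanced_df_bookkeeping(self, rng):
        groups = {k: rng.normal(0, 1, n)
                  for k, n in zip("abcd", (15, 9, 10, 9))}
        res = one_way_anova_tukey(groups)
        assert (res.df1, res.df2) == (3, 39)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova_tukey({"a": [1.0], "b": [1.0, 2.0]})

    def test_posture_category_pattern(self):
        """BS separates from Good, NF does not, in most replicated studies
        at the published category means/SDs and sample sizes."""
        means = {"Good": 0.711, "BS": 0.762, "NF": 0.721, "NB": 0.736}
        sds = {"Good": 0.025, "BS": 0.034, "NF": 0.028, "NB": 0.028}
        ns = {"Good": 15, "BS": 9, "NF": 10, "NB": 9}
        bs_hits = nf_misses = 0
        n_seeds = 50
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            groups = {k: r.normal(means[k], sds[k], ns[k]) for k in means}
            res = one_way_anova_tukey(groups)
            if res.pairwise_p("Good", "BS") < 0.05:
                bs_hits += 1
            if res.pairwise_p("Good", "NF") >= 0.05:
                nf_misses += 1
        assert bs_hits >= 0.8 * n_seeds
        assert nf_misses >= 0.8 * n_seeds


class TestTwoWayAnova:
    @staticmethod
    def _balanced_toy(rng):
        a = np.repeat(["x", "y"], 20)
        b = np.tile(np.repeat(["u", "v"], 10), 2)
        y = rng.normal(0, 1, 40) + (a == "y") * 0.8 + (b == "v") * 0.3
        return y, a, b

    def test_matches_statsmodels_on_full_rank_layout(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y, a, b = self._balanced_toy(rng)
        table = two_way_anova(y, a, b)
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        oracle = sm.stats.anova_lm(smf.ols("y ~ C(a) * C(b)", df).fit(), typ=1)
        for mine, theirs in zip(
            ("factor_a", "factor_b", "interaction", "residual"),
            ("C(a)", "C(b)", "C(a):C(b)", "Residual"),
        ):
            assert table.loc[mine, "sum_sq"] == \
                pytest.approx(oracle.loc[theirs, "sum_sq"], rel=1e-9)
            assert table.loc[mine, "df"] == oracle.loc[theirs, "df"]

    def test_hand_computed_cell_means(self):
        # 2x2 balanced layout with 2 obs/cell and known cell means
        y = np.array([1.0, 1.0, 3.0, 3.0, 2.0, 2.0, 8.0, 8.0])
        a = ["x"] * 4 + ["y"] * 4
        b = ["u", "u", "v", "v"] * 2
        table = two_way_anova(y, a, b)
        # grand mean 3.5; A means 2/5 -> SS_A = 8*1.5^2 = 18
        assert table.loc["factor_a", "sum_sq"] == pytest.approx(18.0)
        # B means 1.5/5.5 -> SS_B = 8*2^2 = 32
        assert table.loc["factor_b", "sum_sq"] == pytest.approx(32.0)
        # cell means 1,3,2,8 -> SS_cells = 2*sum((cell-3.5)^2) = 58; SS_AB = 8
        assert table.loc["interaction", "sum_sq"] == pytest.approx(8.0)
        assert table.loc["residual", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_cell_reduces_interaction_df(self, rng):
        # 3x2 layout with one empty cell: interaction df drops from 2 to 1
        a, b, y = [], [], []
        for ai in "pqr":
            for bi in "uv":
                if (ai, bi) == ("p", "u"):
                    continue
                for _ in range(4):
                    a.append(ai)
                    b.append(bi)
                    y.append(rng.normal())
        table = two_way_anova(np.array(y), a, b)
        assert table.loc["factor_a", "df"] == 2
        assert table.loc["factor_b", "df"] == 1
        assert table.loc["interaction", "df"] == 1
        assert table.loc["residual", "df"] == 20 - 5

    def test_type_i_error_when_no_effects(self):
        rejections = np.zeros(2)
        n_reps = 200
        for seed in range(n_reps):
            r = np.random.default_rng(seed)
            a = r.choice(["x", "y", "z"], 60)
            b = r.choice(["u", "v"], 60)
            y = r.normal(0, 1, 60)
            try:
                table = two_way_anova(y, a, b)
            except ValueError:  # a draw produced an aliased layout
                continue
            rejections += [
                table.loc["factor_a", "PR(>F)"] < 0.05,
                table.loc["factor_b", "PR(>F)"] < 0.05,
            ]
        rates = rejections / n_reps
        assert np.all(rates > 0.01) and np.all(rates < 0.10)


def test_precision_summary_round_trip(rng):
    values = 0.75 * (1 + 0.005 * rng.standard_normal(50))
    s = PrecisionSummary.from_values(values)
    assert s.n == 50
    assert s.cv == pytest.approx(100 * s.sd / s.mean)
    assert s.se_at(3) == pytest.approx(s.sd / np.sqrt(3))
    assert s.min_measurements() >= 1
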