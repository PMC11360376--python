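"""Descriptives, agreement, normality, Welch ANOVA, Games-Howell, BCa, letters."""

import math

import numpy as np
import pytest

from vinemetrics.sensor_stats import (
    DegenerateInputError,
    bca_ci,
    compact_letter_display,
    descriptive,
    games_howell,
    levene_test,
    model2_regression,
    normality_tests,
    pearson_with_test,
    rmse_paired,
    welch_anova,
)


class TestDescriptive:
    def test_simple(self):
        d = descriptive([1.0, 2.0, 3.0])
        assert (d.mean, d.sd, d.cv_percent) == (2.0, 1.0, 50.0)
        assert (d.min, d.max, d.n) == (1.0, 3.0, 3)

    def test_constant(self):
        d = descriptive([2.0, 2.0, 2.0])
        assert d.sd == 0.0 and d.cv_percent == 0.0

    def test_cv_from_table_values(self):
        """Mean 1.57 m, SD 0.17 m gives CV 10.83% (rounded inputs; the
        unrounded source prints 10.84)."""
        cv = 100 * 0.17 / 1.57
        d = descriptive([1.57 - 0.17, 1.57, 1.57 + 0.17])
        # sd of symmetric triple is 0.17, mean 1.57
        assert d.cv_percent == pytest.approx(cv, abs=1e-9)
        assert cv == pytest.approx(10.83, abs=0.02)

    def test_empty_raises(self):
        with pytest.raises(DegenerateInputError):
            descriptive([])


class TestPearson:
    def test_perfect_correlations(self):
        r, p = pearson_with_test([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        r, _ = pearson_with_test([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_sampling_distribution(self, rng):
        n = 10000
        x = rng.normal(size=n)
        y = 0.8 * x + math.sqrt(1 - 0.64) * rng.normal(size=n)
        r, p = pearson_with_test(x, y)
        assert 0.78 <= r <= 0.82
        assert p < 1e-10

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            pearson_with_test([1, 1, 1], [1, 2, 3])


class TestModel2:
    def test_exact_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = model2_regression(x, 2 * x)
        for fit in (res.ols, res.ma, res.sma):
            assert fit.slope == pytest.approx(2.0, abs=1e-12)
            assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.p_value < 1e-10

    def test_sma_closed_form(self, rng):
        """SMA slope = sign(r) sd_y / sd_x regardless of scatter."""
        x = rng.normal(0, 1.0, 200)
        y = 0.5 * x + rng.normal(0, 1.8, 200)
        res = model2_regression(x, y)
        sdx, sdy = np.std(x, ddof=1), np.std(y, ddof=1)
        assert abs(res.sma.slope) == pytest.approx(sdy / sdx, rel=1e-9)
        assert math.copysign(1, res.sma.slope) == math.copysign(1, res.r)

    def test_sma_geometric_mean_identity(self, rng):
        """|SMA| = sqrt(b_yx / b_xy) where b_xy is the inverse-fit slope."""
        x = rng.normal(2, 1, 50)
        y = 1.5 * x + rng.normal(0, 1, 50)
        res = model2_regression(x, y)
        b_yx = np.polyfit(x, y, 1)[0]
        b_xy = np.polyfit(y, x, 1)[0]
        assert abs(res.sma.slope) == pytest.approx(
            math.sqrt(abs(b_yx / b_xy)), rel=1e-9
        )

    def test_r_squared_identity(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        res = model2_regression(x, y)
        assert res.r_squared == pytest.approx(res.r**2, rel=1e-12)

    def test_p_equals_pearson_p(self, rng):
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        res = model2_regression(x, y)
        _, p = pearson_with_test(x, y)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_slope_cis_bracket_estimates(self, rng):
        x = rng.normal(size=80)
        y = 2.0 * x + rng.normal(0, 0.5, 80)
        res = model2_regression(x, y)
        for fit in (res.ols, res.ma, res.sma):
            assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]


class TestRmse:
    def test_closed_forms(self):
        assert rmse_paired([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse_paired([1.1, 2.1], [1.0, 2.0]) == pytest.approx(0.1)
        assert rmse_paired([1, 2, 3], [2, 2, 2]) == pytest.approx(
            math.sqrt(2 / 3)
        )

    def test_length_mismatch(self):
        with pytest.raises(DegenerateInputError):
            rmse_paired([1, 2], [1, 2, 3])


class TestNormality:
    def test_normal_data_mostly_passes(self, rng):
        passed = 0
        for _ in range(100):
            r = normality_tests(rng.normal(size=500))
            passed += (r["ks_p"] > 0.05) and (r["sw_p"] > 0.05)
        assert passed >= 80  # two joint tests at alpha 0.05 each

    def test_uniform_data_rejected(self, rng):
        rejected = 0
        for _ in range(40):
            r = normality_tests(rng.uniform(size=500))
            rejected += r["sw_p"] < 0.05
        assert rejected >= 38

    def test_n3_returns(self):
        r = normality_tests([1.0, 2.0, 4.0])
        assert math.isfinite(r["sw_p"])  # KS needs n >= 4, reported as NaN
        assert math.isnan(r["ks_p"])


class TestLevene:
    def test_equal_deviations_w_zero(self):
        w, p = levene_test([np.array([1.0, 3.0]), np.array([5.0, 7.0])])
        assert w == pytest.approx(0.0)

    def test_unequal_variances_detected(self, rng):
        hits = 0
        for _ in range(20):
            g1 = rng.normal(0, 1, 200)
            g2 = rng.normal(0, 5, 200)
            _, p = levene_test([g1, g2])
            hits += p < 0.001
        assert hits >= 19

    def test_single_group_raises(self):
        with pytest.raises(DegenerateInputError):
            levene_test([np.array([1.0, 2.0])])


class TestWelchAnova:
    def test_identical_means_f_zero(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        res = welch_anova(g)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_equals_welch_t_squared(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.5, 2, 40)
        from scipy import stats

        t, p = stats.ttest_ind(a, b, equal_var=False)
        res = welch_anova([a, b])
        assert res.F == pytest.approx(t**2, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        groups = [rng.normal(m, s, n) for m, s, n in
                  ((0, 1, 20), (0.5, 2, 30), (1.2, 0.5, 25))]
        res = welch_anova(groups)
        df = pd.DataFrame({
            "v": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [20, 30, 25]),
        })
        ref = pg.welch_anova(dv="v", between="g", data=df)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)


class TestGamesHowell:
    def test_identical_groups_share_letter(self):
        g = {"a": np.array([1.0, 2, 3, 4]), "b": np.array([1.0, 2, 3, 4])}
        res = games_howell(g, n_boot=50, seed=0)
        assert res.pairwise[0].p_adjusted > 0.99
        assert res.letters["a"] == res.letters["b"] == "a"

    def test_separated_group_gets_own_letter(self, rng):
        g = {
            "g1": rng.normal(0, 0.1, 20),
            "g2": rng.normal(0, 0.1, 20),
            "g3": rng.normal(10, 0.1, 20),
        }
        res = games_howell(g, n_boot=50, seed=0)
        pw = {(c.group_a, c.group_b): c.p_adjusted for c in res.pairwise}
        assert pw[("g1", "g2")] > 0.05
        assert pw[("g1", "g3")] < 0.001 and pw[("g2", "g3")] < 0.001
        assert res.letters["g1"] == res.letters["g2"]
        assert res.letters["g3"] != res.letters["g1"]

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        groups = {
            "a": rng.normal(0, 1, 18), "b": rng.normal(0.8, 2, 26),
            "c": rng.normal(2.0, 0.6, 22),
        }
        res = games_howell(groups, n_boot=20, seed=0)
        df = pd.DataFrame({
            "v": np.concatenate(list(groups.values())),
            "g": np.repeat(list(groups), [18, 26, 22]),
        })
        ref = pg.pairwise_gameshowell(dv="v", between="g", data=df)
        ours = {(c.group_a, c.group_b): c for c in res.pairwise}
        for _, row in ref.iterrows():
            c = ours[(row["A"], row["B"])]
            assert c.mean_diff == pytest.approx(row["diff"], rel=1e-9)
            assert c.se == pytest.approx(row["se"], rel=1e-9)
            assert c.df == pytest.approx(row["df"], rel=1e-9)
            assert c.p_adjusted == pytest.approx(row["pval"], abs=1e-6)

    def test_symmetry_under_relabeling(self, rng):
        vals = {k: rng.normal(i, 1, 15) for i, k in enumerate("abc")}
        res1 = games_howell(vals, n_boot=20, seed=3)
        res2 = games_howell(dict(reversed(vals.items())), n_boot=20, seed=3)
        p1 = {frozenset((c.group_a, c.group_b)): c.p_adjusted
              for c in res1.pairwise}
        p2 = {frozenset((c.group_a, c.group_b)): c.p_adjusted
              for c in res2.pairwise}
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], rel=1e-12)

    def test_no_flags_when_welch_quiet(self, rng):
        """Equal-mean equal-variance groups: almost never any flagged pair."""
        flagged = 0
        runs = 40
        for i in range(runs):
            g = {k: rng.normal(0, 1, 25) for k in "abc"}
            res = games_howell(g, n_boot=2, seed=i)
            if res.welch.p > 0.2:
                flagged += any(c.p_adjusted < 0.05 for c in res.pairwise)
        assert flagged <= max(1, int(0.05 * runs))


class TestBca:
    def test_contains_point_estimate(self, rng):
        x = rng.normal(3, 1, 40)
        lo, hi = bca_ci((x,), lambda a: np.mean(a), n_boot=500, seed=1)
        assert lo <= np.mean(x) <= hi

    def test_degenerate_constant_groups(self):
        a = np.full(10, 5.0)
        b = np.full(12, 3.0)
        lo, hi = bca_ci((a, b), lambda x, y: np.mean(x) - np.mean(y),
                        n_boot=100, seed=0)
        assert lo == hi == 2.0

    def test_reduces_to_percentile_when_symmetric(self, rng):
        """With zero bias/acceleration (symmetric statistic on symmetric
        data) BCa is close to the simple percentile interval."""
        x = rng.normal(0, 1, 2000)
        lo, hi = bca_ci((x,), lambda a: np.mean(a), n_boot=2000, seed=5)
        boot = np.array([
            np.mean(np.random.default_rng(s).choice(x, x.size))
            for s in range(2000)
        ])
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.02)
        assert hi == pytest.approx(phi, abs=0.02)


class TestCompactLetters:
    def test_chain_structure(self):
        # means a > b > c; only (a, c) differs -> a: a, b: ab, c: b
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        sig = {("a", "c"): True, ("c", "a"): True}
        letters = compact_letter_display(means, sig)
        assert letters["a"] == "a"
        assert set(letters["b"].split(",")) == {"a", "b"}
        assert letters["c"] == "b"

    def test_all_different(self):
        means = {"x": 1.0, "y": 2.0, "z": 3.0}
        sig = {(a, b): True for a in means for b in means if a != b}
        letters = compact_letter_display(means, sig)
        assert letters == {"z": "a", "y": "b", "x": "c"}

    def test_none_different(self):
        means = {"x": 1.0, "y": 2.0}
        letters = compact_letter_display(means, {})
        assert letters["x"] == letters["y"] == "a"
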