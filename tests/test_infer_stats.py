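import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ehrkit.core import EHRFrame
from ehrkit.errors import ValidationError
from ehrkit.infer_stats import (benjamini_hochberg, compare_glm,
                                concordance_ci, cox_ph, fit_glm, g_test,
                                kaplan_meier, logrank_test,
                                rank_features_groups)
from ehrkit.synth import simulate_survival_cohort


def km_oracle(durations, events):
    """Hand product-limit estimator: S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = {}
    s = 1.0
    for t in sorted(set(durations[events])):
        n_at_risk = int((durations >= t).sum())
        d = int(((durations == t) & events).sum())
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


class TestGTestAndBH:
    def test_hand_value(self):
        G, dof, p = g_test([[10, 20], [20, 10]])
        assert G == pytest.approx(6.796, abs=0.001)
        assert dof == 1
        assert p == pytest.approx(0.00914, abs=0.0005)

    def test_matches_scipy_log_likelihood_ratio(self):
        table = np.array([[30, 45, 25], [20, 30, 50]])
        G, dof, p = g_test(table)
        chi2, p2, dof2, _ = stats.chi2_contingency(
            table, lambda_="log-likelihood", correction=False)
        assert G == pytest.approx(chi2)
        assert p == pytest.approx(p2)

    def test_approximates_chi_squared_for_large_counts(self):
        table = np.array([[120, 80], [90, 110]])
        G, _, _ = g_test(table)
        chi2, *_ = stats.chi2_contingency(table, correction=False)
        assert abs(G - chi2) / chi2 < 0.05

    def test_zero_row_dropped(self):
        G, dof, p = g_test([[0, 0], [5, 5]])
        assert (G, dof, p) == (0.0, 0, 1.0)

    def test_bh_hand_stepup(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bh_monotone(self):
        # adjusted p never below raw p, order-preserving, capped at 1
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.random(30)
        np.testing.assert_allclose(
            benjamini_hochberg(p),
            multipletests(p, method="fdr_bh")[1])


class TestRankFeatures:
    def _frame(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        n = 300
        g = np.repeat(["a", "b"], n // 2)
        x = rng.standard_normal(n) + np.where(g == "a", shift, 0.0)
        y = rng.standard_normal(n)
        cat = rng.choice(["u", "v"], size=n)
        X = np.column_stack([x.astype(object), y.astype(object),
                             cat.astype(object)])
        var = pd.DataFrame({"kind": ["numeric", "numeric", "categorical"],
                            "encoding_state": "raw"},
                           index=["x", "y", "flag"])
        f = EHRFrame(X, var=var)
        f.obs["group"] = g
        return f

    def test_identical_distributions_near_null(self):
        # same values in both groups exactly -> t = 0, p = 1
        X = np.tile(np.arange(10.0), 2).reshape(-1, 1)
        var = pd.DataFrame({"kind": "numeric", "encoding_state": "raw"},
                           index=["x"])
        f = EHRFrame(X, var=var)
        f.obs["group"] = np.repeat(["a", "b"], 10)
        t = rank_features_groups(f, "group").table
        row = t[(t["group"] == "a") & (t["variable"] == "x")].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_shifted_feature_ranks_first(self):
        t = rank_features_groups(self._frame(shift=1.5), "group").table
        top = t[t["group"] == "a"].iloc[0]
        assert top["variable"] == "x"
        assert top["p_adjusted"] < 1e-6

    def test_adjusted_ge_raw_and_sorted(self):
        t = rank_features_groups(self._frame(seed=3), "group").table
        assert (t["p_adjusted"] >= t["p_value"] - 1e-15).all()
        for g in ["a", "b"]:
            sub = t[t["group"] == g]
            assert (np.diff(sub["p_adjusted"]) >= -1e-12).all()

    def test_categorical_tested_with_g_test(self):
        t = rank_features_groups(self._frame(), "group").table
        assert (t[t["variable"] == "flag"]["test"] == "g-test").all()

    def test_single_group_rejected(self):
        f = self._frame()
        f.obs["group"] = "a"
        with pytest.raises(ValidationError):
            rank_features_groups(f, "group")


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = kaplan_meier([1, 2, 3], [False, False, False])["all"]
        assert km.survival_at(10) == 1.0
        assert len(km.times) == 0

    def test_three_events_by_hand(self):
        km = kaplan_meier([1, 2, 3], [True, True, True])["all"]
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_duplication_invariance(self):
        d = [1, 2, 2, 5]
        e = [True, False, True, True]
        a = kaplan_meier(d, e)["all"]
        b = kaplan_meier(d * 2, e * 2)["all"]
        np.testing.assert_allclose(a.survival, b.survival)

    def test_exhaustive_small_patterns_match_oracle(self):
        durations = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        for pattern in itertools.product([False, True], repeat=6):
            if not any(pattern):
                continue
            km = kaplan_meier(durations, list(pattern))["all"]
            oracle = km_oracle(durations, pattern)
            got = {t: s for t, s in zip(km.times, km.survival)}
            assert set(got) == set(oracle)
            for t in oracle:
                assert got[t] == pytest.approx(oracle[t])

    def test_confidence_band_brackets_estimate(self):
        rng = np.random.default_rng(2)
        km = kaplan_meier(rng.exponential(1, 100),
                          rng.random(100) < 0.8)["all"]
        assert (km.ci_lower <= km.survival + 1e-12).all()
        assert (km.ci_upper >= km.survival - 1e-12).all()
        assert (km.ci_lower >= 0).all() and (km.ci_upper <= 1).all()

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [True, True])


class TestLogRank:
    def test_identical_groups_null(self):
        d = [1, 2, 3, 4, 5]
        e = [True, True, False, True, True]
        res = logrank_test(d + d, e + e, ["a"] * 5 + ["b"] * 5)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 1

    def test_agrees_with_permutation_null(self):
        rng = np.random.default_rng(3)
        d = rng.exponential(1, 40)
        e = rng.random(40) < 0.8
        g = np.repeat(["a", "b"], 20)
        obs = logrank_test(d, e, g).statistic
        perm = np.array([
            logrank_test(d, e, rng.permutation(g)).statistic
            for _ in range(300)])
        p_perm = (perm >= obs).mean()
        p_chi2 = logrank_test(d, e, g).p_value
        assert abs(p_perm - p_chi2) < 0.12  # Monte-Carlo error at 300 perms

    def test_strong_hazard_difference_detected(self):
        f = simulate_survival_cohort(200, {"a": 1.0, "b": 3.0},
                                     censor_rate=0.1, seed=4)
        M, _ = f.numeric_matrix(["duration", "event"])
        res = logrank_test(M[:, 0], M[:, 1] > 0, f.obs["group"])
        assert res.p_value < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [True, True], ["a", "a"])


class TestCox:
    def test_recovers_log_hazard_ratio_two(self):
        f = simulate_survival_cohort(1000, {"ctrl": 1.0, "treat": 2.0},
                                     censor_rate=0.2, seed=5)
        f.obs["treated"] = (f.obs["group"] == "treat").astype(float)
        res = cox_ph(f, "duration", "event", ["treated"])
        beta = res.summary.loc["treated", "coef"]
        se = res.summary.loc["treated", "se"]
        assert abs(beta - np.log(2)) < 3 * se

    def test_constant_covariate_rejected(self):
        f = simulate_survival_cohort(50, {"a": 1.0}, seed=6)
        f.obs["c"] = 1.0
        with pytest.raises(ValidationError):
            cox_ph(f, "duration", "event", ["c"])

    def test_missing_model_column_rejected(self):
        f = simulate_survival_cohort(50, {"a": 1.0}, seed=7)
        cov = np.ones(50)
        cov[0] = np.nan
        f.obs["c"] = cov
        with pytest.raises(ValidationError):
            cox_ph(f, "duration", "event", ["c"])


class TestConcordance:
    def test_perfect_ordering(self):
        d = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        hz = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # higher risk fails earlier
        c, (lo, hi) = concordance_ci(hz, d, np.ones(5, bool), n_boot=50,
                                     seed=0)
        assert c == 1.0

    def test_sign_reversal_symmetry(self):
        rng = np.random.default_rng(8)
        d = rng.exponential(1, 200)
        e = rng.random(200) < 0.7
        hz = rng.standard_normal(200)
        c1, _ = concordance_ci(np.exp(hz), d, e, n_boot=10, seed=0)
        c2, _ = concordance_ci(np.exp(-hz), d, e, n_boot=10, seed=0)
        assert c1 + c2 == pytest.approx(1.0, abs=1e-9)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(9)
        d = rng.exponential(1, 2000)
        hz = rng.standard_normal(2000)
        c, (lo, hi) = concordance_ci(hz, d, np.ones(2000, bool),
                                     n_boot=200, seed=1)
        assert lo <= 0.5 <= hi
        assert c == pytest.approx(0.5, abs=0.05)

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            concordance_ci([1.0, 2.0], [1.0, 2.0], [False, False])


class TestGLM:
    def _frame(self, seed=0, n=200, beta=1.0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = beta * x + rng.standard_normal(n)
        X = np.column_stack([y, x, z]).astype(np.float64)
        var = pd.DataFrame({"kind": "numeric", "encoding_state": "raw"},
                           index=["y", "x", "z"])
        return EHRFrame(X, var=var)

    def test_gaussian_equals_ols(self):
        import statsmodels.formula.api as smf
        f = self._frame()
        glm = fit_glm(f, "y ~ x", family="gaussian")
        df = pd.DataFrame({"y": f.get_values("y"), "x": f.get_values("x")},
                          dtype=float)
        ols = smf.ols("y ~ x", data=df).fit()
        np.testing.assert_allclose(glm.params.values, ols.params.values,
                                   atol=1e-8)

    def test_intercept_only_is_mean(self):
        f = self._frame(seed=1)
        glm = fit_glm(f, "y ~ 1", family="gaussian")
        assert glm.params["Intercept"] == pytest.approx(
            np.mean(f.get_values("y").astype(float)))

    def test_perfect_fit_zero_deviance(self):
        f = self._frame(seed=2)
        y = 2 * f.get_values("x").astype(float) + 1
        f.set_values("y", y)
        glm = fit_glm(f, "y ~ x", family="gaussian")
        assert glm.deviance == pytest.approx(0.0, abs=1e-12)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            fit_glm(self._frame(), "y ~ x", family="weird")

    def test_compare_equal_models_degenerate(self):
        f = self._frame(seed=3)
        m = fit_glm(f, "y ~ x")
        assert compare_glm(m, m) == 1.0

    def test_compare_true_predictor_significant(self):
        f = self._frame(seed=4, beta=2.0)
        small = fit_glm(f, "y ~ 1")
        large = fit_glm(f, "y ~ x")
        assert compare_glm(large, small) < 1e-3

    def test_compare_non_nested_rejected(self):
        f = self._frame(seed=5)
        with pytest.raises(ValidationError):
            compare_glm(fit_glm(f, "y ~ x"), fit_glm(f, "y ~ z"))

    def test_noise_predictor_p_uniform(self):
        # under the null the LRT p-value is uniform on [0, 1]
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            n = 80
            y = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            X = np.column_stack([y, noise])
            var = pd.DataFrame({"kind": "numeric", "encoding_state": "raw"},
                               index=["y", "w"])
            f = EHRFrame(X, var=var)
            ps.append(compare_glm(fit_glm(f, "y ~ w"), fit_glm(f, "y ~ 1")))
        assert stats.kstest(ps, "uniform").pvalue > 0.01
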