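import numpy as np
import pandas as pd
import pytest

from ehrkit.core import EHRFrame
from ehrkit.errors import DegenerateInputError, ValidationError
from ehrkit.qc import (balanced_sample, clip_features, detect_bias,
                       little_mcar_test, qc_metrics, subsample,
                       summarize_features, winsorize)
from ehrkit.synth import (CategoricalFeature, CohortConfig, NumericFeature,
                          inject_mcar, make_cohort)


def numeric_frame(X, names=None):
    X = np.asarray(X, dtype=np.float64)
    names = names or [f"v{j}" for j in range(X.shape[1])]
    var = pd.DataFrame({"kind": "numeric", "encoding_state": "raw"},
                       index=names)
    return EHRFrame(X, var=var)


class TestQCMetrics:
    def test_toy_counts(self):
        f = numeric_frame([[1, 2], [np.nan, 4], [5, 6]])
        m = qc_metrics(f)
        assert m.var_table.loc["v0", "missing_fraction"] == pytest.approx(1/3)
        assert m.obs_table.iloc[1]["missing_fraction"] == pytest.approx(1/2)
        assert m.total_missing == 1

    def test_complete_frame_all_zero(self):
        m = qc_metrics(numeric_frame([[1, 2], [3, 4]]))
        assert (m.var_table["missing_count"] == 0).all()
        assert (m.obs_table["missing_count"] == 0).all()

    def test_marginal_sums_reconcile(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        X[rng.random((40, 6)) < 0.2] = np.nan
        m = qc_metrics(numeric_frame(X))
        assert m.var_table["missing_count"].sum() == m.total_missing
        assert m.obs_table["missing_count"].sum() == m.total_missing

    def test_mcar_rate_recovered_at_scale(self):
        cfg = CohortConfig(n_patients=10_000,
                           numeric_features=[NumericFeature("x")], seed=3)
        f = inject_mcar(make_cohort(cfg), "x", rate=0.3, seed=4)
        m = qc_metrics(f)
        assert m.var_table.loc["x", "missing_fraction"] == \
            pytest.approx(0.3, abs=0.02)


class TestSummarizeFeatures:
    def test_min_max_mean(self):
        f = numeric_frame([[1], [2], [3]])
        f.obs["patient"] = ["p1", "p1", "p1"]
        out = summarize_features(f, "patient")
        assert out.n_obs == 1
        M, names = out.numeric_matrix()
        got = dict(zip(names, M[0]))
        assert got == {"v0_min": 1.0, "v0_max": 3.0, "v0_mean": 2.0}

    def test_singleton_group(self):
        f = numeric_frame([[7.0], [1.0]])
        f.obs["patient"] = ["a", "b"]
        out = summarize_features(f, "patient")
        M, _ = out.numeric_matrix()
        assert (M[0] == 7.0).all()

    def test_all_missing_group_stays_missing(self):
        f = numeric_frame([[np.nan], [np.nan], [5.0]])
        f.obs["patient"] = ["a", "a", "b"]
        out = summarize_features(f, "patient")
        M, _ = out.numeric_matrix()
        assert np.isnan(M[0]).all()
        assert (M[1] == 5.0).all()


class TestWinsorize:
    def test_zero_limits_identity(self):
        f = numeric_frame([[1], [50], [100]])
        out = winsorize(f, limits=(0, 0))
        np.testing.assert_array_equal(out.numeric_matrix()[0],
                                      f.numeric_matrix()[0])

    def test_quantile_caps_match_oracle(self):
        vals = np.arange(1.0, 101.0)
        f = numeric_frame(vals.reshape(-1, 1))
        out = winsorize(f, limits=(0.05, 0.05))
        M = out.numeric_matrix()[0][:, 0]
        assert M.min() == np.quantile(vals, 0.05, method="higher")
        assert M.max() == np.quantile(vals, 0.95, method="lower")

    def test_constant_column_unchanged(self):
        f = numeric_frame(np.full((10, 1), 3.0))
        out = winsorize(f, limits=(0.2, 0.2))
        assert (out.numeric_matrix()[0] == 3.0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        f = numeric_frame(rng.standard_normal((200, 2)))
        once = winsorize(f, limits=(0.1, 0.1))
        twice = winsorize(once, limits=(0.1, 0.1))
        np.testing.assert_allclose(twice.numeric_matrix()[0],
                                   once.numeric_matrix()[0])

    def test_invalid_limits(self):
        with pytest.raises(ValueError):
            winsorize(numeric_frame([[1.0]]), limits=(0.6, 0.1))


class TestClip:
    def test_toy(self):
        f = numeric_frame([[-5.0], [0.0], [5.0]])
        out = clip_features(f, bounds=(0, 3))
        np.testing.assert_array_equal(out.numeric_matrix()[0][:, 0],
                                      [0, 0, 3])
        assert out.uns["ehrkit"]["clipped"] == 2

    def test_infinite_bounds_identity(self):
        f = numeric_frame([[-5.0], [5.0]])
        out = clip_features(f)
        np.testing.assert_array_equal(out.numeric_matrix()[0],
                                      f.numeric_matrix()[0])
        assert out.uns["ehrkit"]["clipped"] == 0

    def test_missing_untouched_and_idempotent(self):
        f = numeric_frame([[np.nan], [10.0]])
        once = clip_features(f, bounds=(0, 5))
        twice = clip_features(once, bounds=(0, 5))
        assert np.isnan(once.numeric_matrix()[0][0, 0])
        np.testing.assert_array_equal(
            np.nan_to_num(twice.numeric_matrix()[0]),
            np.nan_to_num(once.numeric_matrix()[0]))

    def test_inverted_bounds(self):
        with pytest.raises(ValueError):
            clip_features(numeric_frame([[1.0]]), bounds=(3, 0))


class TestLittleMCAR:
    def test_complete_data_degenerate(self):
        f = numeric_frame(np.random.default_rng(0).standard_normal((20, 3)))
        with pytest.raises(DegenerateInputError):
            little_mcar_test(f)

    def test_dof_two_patterns_by_hand(self):
        # p=3; pattern 1 observes all 3 vars, pattern 2 observes 2
        # dof = (3 + 2) - 3 = 2
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 3))
        X[:20, 2] = np.nan
        res = little_mcar_test(numeric_frame(X))
        assert res.dof == 2
        assert res.n_patterns == 2
        assert res.statistic >= 0
        assert 0 <= res.p_value <= 1

    def test_mcar_not_rejected_mar_rejected(self):
        cfg = CohortConfig(
            n_patients=2000,
            numeric_features=[NumericFeature(f"x{i}") for i in range(3)],
            correlation=0.5, seed=11)
        base = make_cohort(cfg)
        mcar = inject_mcar(base, "x0", 0.25, seed=12)
        from ehrkit.synth import inject_mar
        mar = inject_mar(base, "x0", "x1", seed=13)
        assert little_mcar_test(mcar).p_value > 0.01
        assert little_mcar_test(mar).p_value < 1e-4


class TestDetectBias:
    def _grouped_frame(self, shift, n=10_000, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.choice(["A", "B"], size=n)
        x = rng.standard_normal(n) + np.where(g == "A", shift, 0.0)
        f = numeric_frame(x.reshape(-1, 1), names=["x"])
        f.obs["group"] = g
        return f

    def test_identical_groups_smd_near_zero(self):
        rep = detect_bias(self._grouped_frame(0.0), ["group"])
        assert rep.smd["smd"].abs().max() < 0.05

    def test_one_sd_shift_gives_smd_one(self):
        rep = detect_bias(self._grouped_frame(1.0), ["group"])
        assert rep.smd["smd"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_self_correlation_is_one(self):
        rep = detect_bias(self._grouped_frame(0.0, n=100), ["group"])
        assert rep.correlations.loc["x", "x"] == pytest.approx(1.0)

    def test_numeric_sensitive_rejected(self):
        f = self._grouped_frame(0.0, n=50)
        f.obs["num"] = np.arange(50.0)
        with pytest.raises(ValidationError):
            detect_bias(f, ["num"])

    def test_categorical_differences_and_importance(self):
        rng = np.random.default_rng(7)
        n = 400
        g = rng.choice(["A", "B"], size=n)
        x = rng.standard_normal(n)
        y = 2 * x + rng.standard_normal(n) * 0.1
        X = np.column_stack([x, y]).astype(object)
        cat = np.where(g == "A", "hi", "lo").astype(object)
        X = np.column_stack([X, cat])
        var = pd.DataFrame(
            {"kind": ["numeric", "numeric", "categorical"],
             "encoding_state": "raw"}, index=["x", "y", "flag"])
        f = EHRFrame(X, var=var)
        f.obs["group"] = g
        rep = detect_bias(f, ["group"], target="y")
        assert not rep.categorical_differences.empty
        assert rep.feature_importance.iloc[0]["variable"] == "x"


class TestSampling:
    def test_subsample_sizes_and_determinism(self, mixed_frame):
        cfg = CohortConfig(n_patients=100,
                           numeric_features=[NumericFeature("x")], seed=0)
        f = make_cohort(cfg)
        s1 = subsample(f, 0.5, seed=42)
        s2 = subsample(f, 0.5, seed=42)
        assert s1.n_obs == 50
        assert list(s1.obs_names) == list(s2.obs_names)
        assert subsample(f, 1.0, seed=0).n_obs == 100

    def test_subsample_invalid_fraction(self, mixed_frame):
        with pytest.raises(ValueError):
            subsample(mixed_frame, 0.0, seed=0)

    @pytest.mark.parametrize("method,expected", [("under", 20),
                                                 ("over", 80)])
    def test_balanced_sample_group_sizes(self, method, expected):
        cfg = CohortConfig(
            n_patients=100, numeric_features=[NumericFeature("x")],
            group=CategoricalFeature("arm", ["a", "b"], [0.8, 0.2]),
            seed=8)
        f = make_cohort(cfg)
        counts = f.obs["arm"].value_counts()
        out = balanced_sample(f, "arm", method=method, seed=1)
        got = out.obs["arm"].value_counts()
        assert got["a"] == got["b"]
        target = counts.min() if method == "under" else counts.max()
        assert (got == target).all()
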