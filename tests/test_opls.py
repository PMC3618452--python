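"""OPLS-DA: scaling, fitting, VIP, back-scaling, prediction, Q2."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.pipeline import Pipeline

from metabopls import (
    OPLSDA,
    UnitVarianceScaler,
    backscaled_coefficients,
    fit_oplsda,
    uv_scale,
)


def labels(n_t, n_c):
    return np.array(["treated"] * n_t + ["control"] * n_c)


def random_problem(seed, n=None, p=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(10, 31))
    p = p or int(rng.integers(6, 51))
    X = rng.normal(size=(n, p))
    y = labels(n // 2, n - n // 2)
    rng.shuffle(y)
    return X, y


class TestUnitVarianceScaler:
    def test_two_point_column(self):
        out = UnitVarianceScaler().fit_transform(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-0.7071, 0.7071], atol=1e-4)

    def test_scaled_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        out = UnitVarianceScaler().fit_transform(rng.uniform(0, 9, (12, 30)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_column_dropped_and_recorded(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0), np.arange(5.0) ** 2])
        scaler = UnitVarianceScaler().fit(X)
        assert list(scaler.dropped_columns_) == [1]
        assert scaler.transform(X).shape == (5, 2)

    def test_rescaling_is_noop_on_retained_columns(self):
        rng = np.random.default_rng(1)
        once = UnitVarianceScaler().fit_transform(rng.normal(size=(10, 6)))
        twice = UnitVarianceScaler().fit_transform(once)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_all_constant_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            UnitVarianceScaler().fit(np.ones((5, 3)))

    def test_uv_scale_wrapper_reports_stats(self):
        rng = np.random.default_rng(2)
        X = rng.normal(2.0, 3.0, size=(8, 4))
        sm = uv_scale(X)
        np.testing.assert_allclose(sm.column_means, X.mean(axis=0))
        np.testing.assert_allclose(sm.column_sds, X.std(axis=0, ddof=1))
        assert sm.dropped_columns.size == 0


class TestFit:
    def test_perfect_predictor_gives_r2y_one(self):
        rng = np.random.default_rng(3)
        y = labels(6, 6)
        coded = np.where(y == "treated", 1.0, 2.0)
        yc = coded - coded.mean()
        X = rng.normal(size=(12, 5))
        # noise columns orthogonal to the response in-sample
        X -= np.outer(yc, yc @ X) / (yc @ yc)
        X[:, 0] = yc
        model = OPLSDA(n_orth=0, scale=False, cv_folds=0).fit(X, y)
        assert model.r2y_ == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(model.predict(X), coded, atol=1e-9)
        assert np.all(model.predict_class(X) == y)

    def test_orthogonal_scores_uncorrelated_with_response(self):
        X, y = random_problem(4, n=20, p=30)
        model = OPLSDA(n_orth=3, scale=True, cv_folds=0).fit(X, y)
        coded = np.where(y == "treated", 1.0, 2.0)
        yc = coded - coded.mean()
        for t_o in model.T_o_:
            assert abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc)) < 1e-8

    def test_predictive_weight_unit_norm(self):
        X, y = random_problem(5)
        model = OPLSDA(n_orth=2, cv_folds=0).fit(X, y)
        assert np.linalg.norm(model.w_) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("k", [1, 2])
    def test_prediction_equivalence_with_pls1(self, seed, k):
        """OPLS with 1 predictive + k orthogonal components predicts
        identically to plain NIPALS PLS1 with k+1 components."""
        X, y = random_problem(seed)
        rng = np.random.default_rng(1000 + seed)
        X_new = rng.normal(size=(5, X.shape[1]))
        coded = np.where(y == "treated", 1.0, 2.0)
        opls = OPLSDA(n_orth=k, scale=False, cv_folds=0).fit(X, y)
        pls = PLSRegression(n_components=k + 1, scale=False).fit(X, coded)
        np.testing.assert_allclose(
            opls.predict(X_new), pls.predict(X_new).ravel(), atol=1e-8
        )

    def test_r2x_reaches_one_at_full_rank(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 4))
        y = labels(4, 4)
        model = OPLSDA(n_orth=3, scale=False, cv_folds=0).fit(X, y)
        assert model.r2x_ == pytest.approx(1.0, abs=1e-6)

    def test_too_many_orthogonal_components_is_error(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError):
            OPLSDA(n_orth=5, scale=False, cv_folds=0).fit(X, labels(3, 3))

    def test_single_class_rejected(self):
        X = np.random.default_rng(8).normal(size=(6, 4))
        with pytest.raises(ValueError, match="both classes"):
            OPLSDA(cv_folds=0).fit(X, np.array(["treated"] * 6))


class TestVip:
    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(9)
        y = labels(5, 5)
        coded = np.where(y == "treated", 1.0, 2.0)
        X = (coded - coded.mean())[:, None] + rng.normal(0, 0.1, size=(10, 1))
        model = OPLSDA(n_orth=0, scale=True, cv_folds=0).fit(X, y)
        assert model.vip_[0] == pytest.approx(1.0)

    def test_identical_informative_columns_share_vip_one(self):
        rng = np.random.default_rng(10)
        y = labels(6, 6)
        coded = np.where(y == "treated", 1.0, 2.0)
        col = coded - coded.mean() + rng.normal(0, 0.2, 12)
        X = np.tile(col[:, None], (1, 4))
        model = OPLSDA(n_orth=0, scale=True, cv_folds=0).fit(X, y)
        np.testing.assert_allclose(model.vip_, 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_squared_vip_is_one(self, seed):
        X, y = random_problem(seed + 20)
        model = OPLSDA(n_orth=1, cv_folds=0).fit(X, y)
        assert np.sum(model.vip_**2) == pytest.approx(model.vip_.size, abs=1e-9)


class TestBackscaling:
    def test_unit_sds_leave_coefficients_unchanged(self):
        X, y = random_problem(30, n=16, p=8)
        model = OPLSDA(n_orth=1, scale=False, cv_folds=0).fit(X, y)
        _, back, _, _ = backscaled_coefficients(model)
        np.testing.assert_allclose(back, model.coef_)

    def test_color_endpoints_span_unit_interval(self):
        X, y = random_problem(31, n=18, p=12)
        model = OPLSDA(n_orth=1, scale=True, cv_folds=0).fit(X, y)
        _, _, v, color = backscaled_coefficients(model)
        assert color[np.argmin(v)] == 0.0
        assert color[np.argmax(v)] == 1.0
        assert np.all((color >= 0) & (color <= 1))

    def test_equal_vips_map_to_half(self):
        model = OPLSDA(n_orth=0, scale=False, cv_folds=0)
        rng = np.random.default_rng(32)
        y = labels(6, 6)
        coded = np.where(y == "treated", 1.0, 2.0)
        col = coded - coded.mean() + rng.normal(0, 0.2, 12)
        model.fit(np.tile(col[:, None], (1, 3)), y)
        _, _, _, color = backscaled_coefficients(model)
        np.testing.assert_array_equal(color, 0.5)

    def test_sign_matches_group_mean_difference_on_planted_data(self):
        """Back-scaled coefficient sign agrees with the direction of the
        group mean difference wherever the effect is clear (|t| > 2)."""
        rng = np.random.default_rng(33)
        n_t, n_c, p = 12, 11, 40
        y = labels(n_t, n_c)
        X = rng.normal(10.0, 1.0, size=(23, p))
        X[:n_t, :5] *= 1.3
        X[:n_t, 5:10] *= 0.7
        model = OPLSDA(n_orth=1, scale=True, cv_folds=0).fit(X, y)
        _, back, _, _ = backscaled_coefficients(model)
        from scipy.stats import ttest_ind

        t = ttest_ind(X[:n_t], X[n_t:], axis=0, equal_var=True).statistic
        diff = X[:n_t].mean(axis=0) - X[n_t:].mean(axis=0)
        clear = np.abs(t) > 2
        assert clear.sum() >= 10
        # coding is 1=treated, 2=control, so an elevated bucket pushes the
        # prediction down: coefficient sign is opposite the mean difference
        assert np.all(np.sign(back[clear]) == -np.sign(diff[clear]))

    def test_bin_centers_filtered_to_retained_columns(self):
        X, y = random_problem(34, n=14, p=6)
        X[:, 2] = 7.0  # constant -> dropped at scaling
        model = OPLSDA(n_orth=1, scale=True, cv_folds=0).fit(X, y)
        ppm, back, v, color = backscaled_coefficients(model, np.arange(6.0))
        assert list(ppm) == [0, 1, 3, 4, 5]
        assert back.size == v.size == color.size == 5


class TestPredict:
    def test_prediction_invariant_to_dropped_column_value(self):
        X, y = random_problem(40, n=16, p=10)
        X[:, 4] = 2.5
        model = OPLSDA(n_orth=1, scale=True, cv_folds=0).fit(X, y)
        X_new = np.random.default_rng(41).normal(size=(4, 10))
        base = model.predict(X_new)
        X_mod = X_new.copy()
        X_mod[:, 4] = -99.0
        np.testing.assert_allclose(model.predict(X_mod), base, atol=1e-12)

    def test_column_mismatch_is_error(self):
        X, y = random_problem(42, n=12, p=8)
        model = OPLSDA(cv_folds=0).fit(X, y)
        with pytest.raises(ValueError, match="columns"):
            model.predict(X[:, :5])

    def test_held_out_predictions_match_refit_and_project_oracle(self):
        """Predictions on held-out rows equal an explicit refit-then-project
        loop that applies the training scaler and orthogonal filter by hand."""
        X, y = random_problem(43, n=20, p=12)
        train, test = np.arange(14), np.arange(14, 20)
        model = OPLSDA(n_orth=2, scale=True, cv_folds=0).fit(X[train], y[train])

        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        Xs = (X[test] - mu) / sd
        for w_o, p_o in zip(model.W_o_, model.P_o_):
            Xs = Xs - np.outer(Xs @ w_o, p_o)
        oracle = (Xs @ model.w_) * model.c_ + model.y_mean_
        np.testing.assert_allclose(model.predict(X[test]), oracle, atol=1e-10)

    def test_tie_at_cutoff_goes_to_control(self):
        model = OPLSDA(cv_folds=0, scale=False)
        model.scaler_ = None
        model.x_mean_ = np.zeros(1)
        model.n_features_in_ = 1
        model.W_o_ = np.empty((0, 1))
        model.P_o_ = np.empty((0, 1))
        model.w_ = np.array([1.0])
        model.c_ = 1.0
        model.y_mean_ = 1.5
        # centered score 0 -> prediction exactly at the 1.5 cutoff
        assert model.predict_class(np.array([[0.0]]))[0] == "control"


class TestQ2:
    def test_q2_matches_brute_force_fold_loop(self):
        X, y = random_problem(50, n=21, p=15)
        model = OPLSDA(n_orth=1, scale=True, cv_folds=7, seed=5).fit(X, y)

        coded = np.where(y == "treated", 1.0, 2.0)
        rng = np.random.default_rng(5)
        perm = rng.permutation(21)
        fold = np.empty(21, int)
        fold[perm] = np.arange(21) % 7
        press = 0.0
        for f in range(7):
            tr, te = fold != f, fold == f
            sub = OPLSDA(n_orth=1, scale=True, cv_folds=0).fit(X[tr], y[tr])
            press += np.sum((coded[te] - sub.predict(X[te])) ** 2)
        oracle = 1 - press / np.sum((coded - coded.mean()) ** 2)
        assert model.q2_ == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_q2_never_exceeds_r2y(self, seed):
        X, y = random_problem(60 + seed)
        model = OPLSDA(n_orth=1, cv_folds=5, seed=seed).fit(X, y)
        assert model.q2_ <= model.r2y_ + 1e-9

    def test_cv_folds_larger_than_n_is_error(self):
        X, y = random_problem(70, n=10, p=8)
        with pytest.raises(ValueError, match="cv_folds"):
            OPLSDA(cv_folds=11).fit(X, y)


class TestSklearnInterop:
    def test_get_set_params_roundtrip(self):
        model = OPLSDA(n_orth=2, cv_folds=5, seed=3)
        params = model.get_params()
        assert params["n_orth"] == 2
        model.set_params(n_orth=1, seed=9)
        assert model.n_orth == 1 and model.seed == 9
        with pytest.raises(ValueError, match="invalid parameter"):
            model.set_params(bogus=1)

    def test_composes_with_sklearn_pipeline(self):
        X, y = random_problem(80, n=18, p=10)
        pipe = Pipeline(
            [
                ("scale", UnitVarianceScaler()),
                ("opls", OPLSDA(n_orth=1, scale=False, cv_folds=0)),
            ]
        )
        pipe.fit(X, y)
        direct = OPLSDA(n_orth=1, scale=True, cv_folds=0).fit(X, y)
        np.testing.assert_allclose(pipe.predict(X), direct.predict(X), atol=1e-10)


def test_fit_oplsda_wrapper_matches_class(example_cohort_table):
    table, _ = example_cohort_table
    model = fit_oplsda(table.matrix, np.asarray(table.groups), cv_folds=0, seed=1)
    assert 0 <= model.r2x_ <= 1
    assert 0 <= model.r2y_ <= 1
    assert np.sum(model.vip_**2) == pytest.approx(model.vip_.size, abs=1e-9)
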