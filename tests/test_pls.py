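"""NIPALS PLS1: fitting, prediction, cross-validation, validation metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import TRUE_DESCRIPTORS, make_study
from nanoqspr.pls import (
    ValidationReport,
    explained_variance,
    export_interpretation,
    external_validation,
    fit_pls,
    fitted_statistics,
    loo_cv,
    predict,
    rmse_cv_per_lv,
    select_n_lvs,
)


def linear_instance(rng, n=30, p=4, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 1.5 + X @ beta + noise * rng.normal(size=n)
    return X, y, beta


class TestFit:
    def test_exact_recovery_of_noiseless_linear_response(self, rng):
        X, y, _ = linear_instance(rng)
        model = fit_pls(X, y, n_lv=4)
        r2, rmse_c = fitted_statistics(model, X, y)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert rmse_c == pytest.approx(0.0, abs=1e-10)

    def test_full_rank_pls_equals_ordinary_least_squares(self, rng):
        X, y, _ = linear_instance(rng, n=10, p=3, noise=0.7)
        model = fit_pls(X, y, n_lv=3)
        design = np.column_stack([np.ones(10), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(model.intercept, beta[0], atol=1e-8)
        assert np.allclose(model.coef_original, beta[1:], atol=1e-8)

    def test_full_rank_agrees_with_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, y, _ = linear_instance(rng, n=25, p=6, noise=1.0)
        for n_lv in (1, 2, 4):
            model = fit_pls(X, y, n_lv=n_lv)
            ref = PLSRegression(n_components=n_lv, scale=True).fit(X, y)
            assert np.allclose(
                predict(model, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_single_descriptor_gives_simple_regression_slope(self, rng):
        x = rng.normal(size=20)
        y = 3.0 - 2.0 * x + 0.1 * rng.normal(size=20)
        model = fit_pls(x[:, None], y, n_lv=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coef_original[0] == pytest.approx(slope, abs=1e-10)

    def test_scores_are_mutually_orthogonal(self, rng):
        X, y, _ = linear_instance(rng, n=40, p=6, noise=1.0)
        model = fit_pls(X, y, n_lv=4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_excessive_lv_count_raises(self, rng):
        X, y, _ = linear_instance(rng, n=10, p=3)
        with pytest.raises(ValueError):
            fit_pls(X, y, n_lv=4)
        X_rank_def = np.column_stack([X[:, 0], X[:, 0], X[:, 1]])
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            fit_pls(X_rank_def, y, n_lv=3)

    def test_non_finite_input_raises(self, rng):
        X, y, _ = linear_instance(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_pls(X, y, n_lv=2)


class TestPredict:
    def test_training_predictions_match_residual_bookkeeping(self, rng):
        X, y, _ = linear_instance(rng, noise=0.5)
        model = fit_pls(X, y, n_lv=3)
        yhat = predict(model, X)
        r2, _ = fitted_statistics(model, X, y)
        tss = np.sum((y - y.mean()) ** 2)
        assert 1 - np.sum((y - yhat) ** 2) / tss == pytest.approx(r2)

    def test_column_mean_row_predicts_training_mean(self, rng):
        X, y, _ = linear_instance(rng, noise=1.0)
        for n_lv in (1, 2, 4):
            model = fit_pls(X, y, n_lv=n_lv)
            yhat = predict(model, X.mean(axis=0)[None, :])
            assert yhat[0] == pytest.approx(y.mean())

    def test_missing_descriptor_column_is_named(self, rng):
        X, y, _ = linear_instance(rng)
        frame = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        model = fit_pls(frame, y, n_lv=2)
        with pytest.raises(KeyError, match="d"):
            predict(model, frame[["a", "b", "c"]])

    def test_zero_noise_synthetic_recovers_true_coefficients(self, noiseless_study):
        table, split, train, val, params = noiseless_study
        model = fit_pls(train[TRUE_DESCRIPTORS], train["E_ads"], n_lv=4)
        c0, *cs = params.true_coefficients
        assert model.intercept == pytest.approx(c0, abs=1e-8)
        assert np.allclose(model.coef_original, cs, atol=1e-8)


class TestLooCV:
    def test_perfect_model_has_unit_q2(self, rng):
        X, y, _ = linear_instance(rng, n=15, p=3)
        q2, rmse = loo_cv(X, y, n_lv=3)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        assert rmse == pytest.approx(0.0, abs=1e-8)

    def test_three_point_instance_matches_hand_computation(self):
        # folds are two-point simple regressions: excluding each of
        # (0,0),(1,1),(2,3) in turn predicts -1, 1.5, 2 for the held-out
        # point, so PRESS = 1 + 0.25 + 1 and TSS about the mean 4/3 is 14/3
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 3.0])
        q2, rmse = loo_cv(x, y, n_lv=1)
        assert q2 == pytest.approx(1.0 - 2.25 / (14.0 / 3.0), abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(0.75), abs=1e-12)

    def test_batched_folds_agree_with_naive_refit_loop(self, rng):
        X, y, _ = linear_instance(rng, n=20, p=4, noise=1.0)
        n_lv = 3
        press = 0.0
        for f in range(20):
            keep = np.delete(np.arange(20), f)
            fold = fit_pls(X[keep], y[keep], n_lv=n_lv)
            press += (y[f] - predict(fold, X[f][None, :])[0]) ** 2
        q2, rmse = loo_cv(X, y, n_lv=n_lv)
        tss = np.sum((y - y.mean()) ** 2)
        assert q2 == pytest.approx(1 - press / tss, abs=1e-9)
        assert rmse == pytest.approx(np.sqrt(press / 20), abs=1e-9)

    def test_pure_noise_has_nonpositive_q2_in_expectation(self):
        q2s = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 3))
            y = r.normal(size=40)
            q2s.append(loo_cv(X, y, n_lv=1)[0])
        assert np.mean(q2s) < 0.0

    def test_tiny_sample_raises(self, rng):
        with pytest.raises(ValueError):
            loo_cv(rng.normal(size=(2, 2)), np.array([1.0, 2.0]), n_lv=1)


class TestSelectNLvs:
    def test_noiseless_four_descriptor_data_needs_four_lvs(self, rng):
        X, y, _ = linear_instance(rng, n=30, p=4)
        assert select_n_lvs(X, y, max_lv=4) == 4

    def test_single_descriptor_selects_one(self, rng):
        x = rng.normal(size=(20, 1))
        y = 2 * x.ravel() + rng.normal(size=20)
        assert select_n_lvs(x, y, max_lv=1) == 1

    def test_default_synthetic_study_selects_four(self, all_congeners):
        _, _, train, _, _ = make_study(all_congeners, noise_sd=0.3, data_seed=11)
        assert select_n_lvs(train[TRUE_DESCRIPTORS], train["E_ads"], max_lv=4) == 4

    def test_rmse_cv_curve_has_one_entry_per_lv(self, rng):
        X, y, _ = linear_instance(rng, n=25, p=5, noise=0.5)
        assert len(rmse_cv_per_lv(X, y, max_lv=5)) == 5


class TestExternalValidation:
    def test_perfect_predictions(self, rng):
        X, y, _ = linear_instance(rng)
        model = fit_pls(X, y, n_lv=4)
        q2, rmse_p = external_validation(model, X, y)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        assert rmse_p == pytest.approx(0.0, abs=1e-8)

    def test_three_point_hand_instance(self):
        # training: y = x through (0..3); validation (4, 4.5), (5, 5.5):
        # predictions 4, 5 give PRESS 0.5 and denominator 25 about the
        # training mean 1.5
        X = np.arange(4.0)[:, None]
        model = fit_pls(X, np.arange(4.0), n_lv=1)
        q2, rmse_p = external_validation(
            model, np.array([[4.0], [5.0]]), np.array([4.5, 5.5])
        )
        assert q2 == pytest.approx(1.0 - 0.5 / 25.0, abs=1e-10)
        assert rmse_p == pytest.approx(0.5, abs=1e-10)

    def test_predicting_the_training_mean_scores_zero(self):
        rng = np.random.default_rng(0)
        X, y, _ = linear_instance(rng, n=12, p=2, noise=0.5)
        model = fit_pls(X, y, n_lv=2)
        # a validation design at the training centroid predicts y_mean
        X_val = np.tile(X.mean(axis=0), (5, 1))
        y_val = y.mean() + rng.normal(size=5)
        q2, _ = external_validation(model, X_val, y_val)
        assert q2 == pytest.approx(0.0, abs=1e-10)

    def test_empty_validation_set_raises(self, rng):
        X, y, _ = linear_instance(rng)
        model = fit_pls(X, y, n_lv=2)
        with pytest.raises(ValueError):
            external_validation(model, np.empty((0, 4)), np.array([]))


class TestExplainedVariance:
    def test_orthonormal_descriptors_give_equal_share_to_the_single_lv(self, rng):
        # with orthogonal descriptors the PLS1 Krylov space is
        # one-dimensional: the first LV already is the least-squares
        # direction and carries exactly 1/p of the X variance; further
        # components cannot be extracted
        raw = rng.normal(size=(30, 4))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = Q @ rng.normal(size=4) + 0.1 * rng.normal(size=30)
        model = fit_pls(Q, y, n_lv=1)
        assert model.explained_x_variance[0] == pytest.approx(25.0, abs=1e-8)
        with pytest.raises(np.linalg.LinAlgError):
            fit_pls(Q, y, n_lv=2)

    def test_totals_bounded_by_parseval(self, rng):
        X, y, _ = linear_instance(rng, n=25, p=6, noise=1.0)
        model = fit_pls(X, y, n_lv=4)
        assert sum(model.explained_x_variance) <= 100.0 + 1e-9
        assert sum(model.explained_y_variance) <= 100.0 + 1e-9
        assert all(v >= -1e-12 for v in model.explained_x_variance)

    def test_recomputation_matches_fit_time_values(self, rng):
        X, y, _ = linear_instance(rng, noise=0.5)
        model = fit_pls(X, y, n_lv=3)
        x_pct, y_pct = explained_variance(model, X, y)
        assert np.allclose(x_pct, model.explained_x_variance, atol=1e-9)
        assert np.allclose(y_pct, model.explained_y_variance, atol=1e-9)

    def test_zero_noise_synthetic_run_explains_nearly_all_y(self, noiseless_study):
        _, _, train, _, _ = noiseless_study
        model = fit_pls(train[TRUE_DESCRIPTORS], train["E_ads"], n_lv=4)
        assert sum(model.explained_y_variance) > 99.0


class TestInterpretationExport:
    def test_loading_and_score_table_shapes(self, noiseless_study):
        _, split, train, val, _ = noiseless_study
        model = fit_pls(train[TRUE_DESCRIPTORS], train["E_ads"], n_lv=4)
        loadings, scores = export_interpretation(
            model, train[TRUE_DESCRIPTORS], val[TRUE_DESCRIPTORS],
            train_labels=train["index"], val_labels=val["index"],
        )
        assert loadings.shape == (4, 4)
        assert len(scores) == len(train) + len(val)
        assert set(scores["set_label"]) == {"training", "validation"}

    def test_validation_scores_come_from_projection(self, noiseless_study):
        from nanoqspr.pls import project_scores

        _, split, train, val, _ = noiseless_study
        model = fit_pls(train[TRUE_DESCRIPTORS], train["E_ads"], n_lv=4)
        _, scores = export_interpretation(
            model, train[TRUE_DESCRIPTORS], val[TRUE_DESCRIPTORS]
        )
        val_scores = scores[scores["set_label"] == "validation"]
        expected = project_scores(model, val[TRUE_DESCRIPTORS])
        assert np.allclose(val_scores[["LV1", "LV2", "LV3", "LV4"]], expected)

    def test_lv1_loading_direction_is_seed_stable_up_to_sign_flip(self, all_congeners):
        # different seeds give different nuisance tables and hence
        # different Kennard-Stone training sets, but the leading loading
        # direction of the noiseless model must stay put (up to a global
        # sign flip; individually near-zero loadings may wobble)
        for seed in range(10):
            _, _, train, _, _ = make_study(all_congeners, noise_sd=0.0, data_seed=seed)
            model = fit_pls(train[TRUE_DESCRIPTORS], train["E_ads"], n_lv=4)
            v = model.x_loadings[:, 0]  # order: nH, TE, Dx, Dy
            if v[0] > 0:
                v = -v
            assert v[0] < 0 and v[1] < 0 and v[2] > 0


class TestValidationReport:
    def test_inverted_fit_warns_instead_of_failing(self):
        with pytest.warns(UserWarning, match="Q2cv"):
            ValidationReport(
                r2=0.5, q2_cv=0.9, q2_ext=0.4, rmse_c=1.0, rmse_cv=1.0, rmse_p=1.0
            )

    def test_text_block_carries_all_statistics(self):
        rep = ValidationReport(0.99, 0.95, 0.9, 0.2, 0.4, 0.6)
        text = rep.to_text()
        for token in ("R2", "Q2cv", "Q2ext", "RMSEc", "RMSEcv", "RMSEp"):
            assert token in text
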