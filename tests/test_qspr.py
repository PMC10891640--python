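"""QSPR layer: descriptor preparation, OLS/PCR, LOO cross-validation,
forward selection, validation reporting."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

from photoqspr import (OLSRegressor, PCRRegressor, autoscale,
                       drop_constant_columns, fit_ols, fit_pcr, forward_select,
                       loo_cv, simulate_qspr, validate)
from photoqspr.fixtures import calibration_response


class TestDropConstantColumns:
    def test_zero_column_removed(self):
        x = np.ones((5, 5))
        x[:, :4] = np.random.default_rng(0).normal(size=(5, 4))
        x[:, 4] = 0.0
        red, removed = drop_constant_columns(x)
        assert red.shape == (5, 4) and removed == ["4"]

    def test_identity_when_no_constant(self):
        x = np.random.default_rng(1).normal(size=(6, 3))
        red, removed = drop_constant_columns(x)
        npt.assert_array_equal(red, x)
        assert removed == []

    def test_large_screening_matrix(self):
        """A 1875-column matrix with 448 constant columns reduces to 1427,
        mirroring the screening step of a full descriptor block."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 1875))
        const_idx = rng.choice(1875, size=448, replace=False)
        x[:, const_idx] = 7.0
        red, removed = drop_constant_columns(x)
        assert red.shape[1] == 1427 and len(removed) == 448

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            drop_constant_columns(np.ones((4, 3)))


class TestAutoscale:
    def test_three_point_column(self):
        xs, m, s = autoscale(np.array([[1.0], [2.0], [3.0]]))
        npt.assert_allclose(xs.ravel(), [-1.0, 0.0, 1.0])
        assert (m[0], s[0]) == (2.0, 1.0)

    def test_idempotent(self):
        x = np.random.default_rng(3).normal(size=(10, 4))
        xs, _, _ = autoscale(x)
        xs2, _, _ = autoscale(xs)
        npt.assert_allclose(xs, xs2, atol=1e-12)

    def test_fixture_column_scales_to_unit(self):
        xcal, _ = calibration_response()
        xs, _, _ = autoscale(xcal)
        assert xs[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert xs[:, 0].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            autoscale(np.ones((5, 2)))


class TestOLS:
    def test_exact_line(self):
        x = np.arange(5.0).reshape(-1, 1)
        model = fit_ols(x, 2 * x.ravel() + 1)
        assert model.coef_[0] == pytest.approx(2.0)
        assert model.intercept_ == pytest.approx(1.0)

    def test_constant_response(self):
        x = np.random.default_rng(4).normal(size=(8, 3))
        model = fit_ols(x, np.full(8, 3.3))
        npt.assert_allclose(model.coef_, 0.0, atol=1e-10)
        assert model.intercept_ == pytest.approx(3.3)

    def test_matches_normal_equations_oracle(self):
        """lstsq solution equals the brute-force (X'X)^-1 X'y solution on a
        well-posed random problem."""
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(10, 3)), rng.normal(size=10)
        model = fit_ols(x, y)
        a = np.column_stack([np.ones(10), x])
        beta = np.linalg.inv(a.T @ a) @ a.T @ y
        npt.assert_allclose(np.r_[model.intercept_, model.coef_], beta, rtol=1e-8)

    def test_rank_deficient_warns_and_returns_min_norm(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5, 8))  # p > n
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = fit_ols(x, rng.normal(size=5))
        assert np.all(np.isfinite(model.coef_))

    def test_bw_is_sd_weighted(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 2)) * np.array([1.0, 100.0])
        model = fit_ols(x, x[:, 0] + 0.01 * x[:, 1])
        npt.assert_allclose(model.bw_, model.coef_ * x.std(axis=0, ddof=1))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            fit_ols(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]))


class TestPCR:
    def test_full_rank_equals_ols(self):
        sim = simulate_qspr(15, 4, {0: 2.0, 2: -1.0}, noise_sd=0.2, seed=8)
        ols, pcr = fit_ols(sim.X, sim.y), fit_pcr(sim.X, sim.y, 4)
        npt.assert_allclose(ols.predict(sim.X), pcr.predict(sim.X), atol=1e-8)

    def test_single_component_fits_pc1_response(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=20)
        x = np.column_stack([base, 2 * base, -base]) + rng.normal(0, 1e-9, (20, 3))
        y = 3.0 * base
        model = fit_pcr(x, y, 1)
        npt.assert_allclose(model.predict(x), y, atol=1e-5)

    def test_scale_invariance_of_predictions(self):
        sim = simulate_qspr(15, 4, {0: 2.0}, noise_sd=0.2, seed=10)
        x2 = sim.X.copy()
        x2.iloc[:, 1] *= 10.0
        p1 = fit_pcr(sim.X, sim.y, 3).predict(sim.X)
        p2 = fit_pcr(x2, sim.y, 3).predict(x2)
        npt.assert_allclose(p1, p2, atol=1e-10)

    @pytest.mark.parametrize("m", [0, 20])
    def test_component_count_out_of_range(self, m):
        sim = simulate_qspr(10, 4, {0: 1.0}, seed=0)
        with pytest.raises(ValueError):
            fit_pcr(sim.X, sim.y, m)


class TestLOO:
    def test_collinear_points_have_zero_rmsecv(self):
        x = np.arange(6.0).reshape(-1, 1)
        rmsecv, preds = loo_cv(x, 3 * x.ravel() + 2)
        assert rmsecv == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_refit_loop(self):
        """LOO predictions are bitwise-identical to an explicit refit loop."""
        sim = simulate_qspr(12, 3, {0: 1.0}, noise_sd=0.5, seed=11)
        x, y = sim.X.to_numpy(), sim.y.to_numpy()
        _, preds = loo_cv(x, y)
        manual = np.array([
            OLSRegressor().fit(np.delete(x, i, 0), np.delete(y, i)).predict(x[i:i + 1])[0]
            for i in range(12)
        ])
        npt.assert_array_equal(preds, manual)

    def test_rmsecv_tracks_noise_level(self):
        """For a well-determined model, RMSECV lands in [0.5 sigma, 2 sigma]."""
        sigma = 0.3
        sim = simulate_qspr(40, 3, {0: 5.0, 1: -2.0}, noise_sd=sigma, seed=12)
        rmsecv, _ = loo_cv(sim.X, sim.y)
        assert 0.5 * sigma <= rmsecv <= 2.0 * sigma

    def test_works_with_pcr_refitting_scaler_per_fold(self):
        sim = simulate_qspr(15, 5, {0: 2.0}, noise_sd=0.2, seed=13)
        rmsecv, preds = loo_cv(sim.X, sim.y, PCRRegressor(3))
        assert np.all(np.isfinite(preds)) and rmsecv > 0


class TestForwardSelect:
    def test_perfectly_correlated_variable_enters_first(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(15, 6))
        y = 4.0 * x[:, 3]
        trace = forward_select(x, y, max_vars=2)
        assert trace.selected_indices[0] == 3

    def test_first_pick_matches_correlation_ranking_oracle(self):
        sim = simulate_qspr(20, 10, {2: 3.0, 7: -2.0}, noise_sd=0.5, seed=15)
        x, y = sim.X.to_numpy(), sim.y.to_numpy()
        corr = [abs(np.corrcoef(x[:, j], y)[0, 1]) for j in range(10)]
        trace = forward_select(x, y, max_vars=1)
        assert trace.selected_indices[0] == int(np.argmax(corr))

    def test_planted_variables_selected_before_noise(self):
        """Three strong informative columns in a 20x50 problem enter before
        any pure-noise column."""
        sim = simulate_qspr(20, 50, {3: 5.0, 17: -4.0, 40: 3.0}, noise_sd=0.05, seed=7)
        trace = forward_select(sim.X, sim.y, max_vars=5)
        assert set(trace.selected_indices[:3]) == {3, 17, 40}

    def test_recovers_sparse_model_and_coefficients(self):
        """n=40, small noise: selection ⊇ planted set, refit coefficients
        within 5% of truth."""
        truth = {3: 5.0, 17: -4.0, 40: 3.0}
        sim = simulate_qspr(40, 50, truth, noise_sd=0.01, seed=11)
        trace = forward_select(sim.X, sim.y, max_vars=6)
        assert set(truth) <= set(trace.selected_indices)
        model = OLSRegressor().fit(sim.X.iloc[:, trace.selected_indices], sim.y)
        for j, coef in truth.items():
            fitted = model.coef_[trace.selected_indices.index(j)]
            assert fitted == pytest.approx(coef, rel=0.05)

    def test_rmsecv_path_non_increasing(self):
        sim = simulate_qspr(20, 10, {0: 3.0, 5: 2.0}, noise_sd=0.2, seed=16)
        trace = forward_select(sim.X, sim.y)
        assert np.all(np.diff(trace.rmsecv_path) < 0)

    def test_tie_broken_by_column_order(self):
        x = np.random.default_rng(17).normal(size=(10, 1))
        xx = np.column_stack([x, x])  # identical columns
        trace = forward_select(xx, 2 * x.ravel(), max_vars=1)
        assert trace.selected_indices == [0]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            forward_select(np.empty((5, 0)), np.zeros(5))


class TestPredictAlignment:
    def test_permuted_columns_give_identical_predictions(self):
        sim = simulate_qspr(10, 4, {0: 2.0, 3: 1.0}, noise_sd=0.1, seed=18)
        model = fit_ols(sim.X, sim.y)
        shuffled = sim.X[list(sim.X.columns[::-1])]
        npt.assert_allclose(model.predict(sim.X), model.predict(shuffled))

    def test_missing_column_rejected(self):
        sim = simulate_qspr(10, 3, {0: 1.0}, seed=19)
        model = fit_ols(sim.X, sim.y)
        with pytest.raises(ValueError, match="missing"):
            model.predict(sim.X.drop(columns=[sim.X.columns[1]]))

    def test_exact_fit_predicts_training_response(self):
        sim = simulate_qspr(10, 2, {0: 1.5, 1: -0.5}, noise_sd=0.0, seed=20)
        model = fit_ols(sim.X, sim.y)
        npt.assert_allclose(model.predict(sim.X), sim.y, atol=1e-10)


class TestValidate:
    def test_perfect_prediction(self):
        rep = validate([1.0, 2.0], [1.0, 2.0])
        assert rep.rmsep == 0.0
        npt.assert_allclose(rep.table["error_percent"], 0.0)

    @pytest.mark.parametrize("exp,pred,printed", [
        (1.231, 1.226, -0.400),   # small relative gap
        (0.264, 0.228, -13.662),  # large relative gap
    ])
    def test_error_percent_matches_reference_rows(self, exp, pred, printed):
        """Recomputed relative errors agree with reference-table rows to
        within the rounding of the printed rates."""
        rep = validate([exp], [pred])
        assert rep.table["error_percent"].iloc[0] == pytest.approx(printed, abs=0.15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            validate([1.0], [1.0, 2.0])

    def test_aggregates_recomputable_from_rows(self):
        rng = np.random.default_rng(21)
        exp = np.abs(rng.normal(1, 0.2, 8))
        pred = exp * (1 + rng.normal(0, 0.05, 8))
        rep = validate(exp, pred)
        err = rep.table["error_percent"].to_numpy()
        assert rep.mean_abs_error_percent == pytest.approx(np.mean(np.abs(err)))
        assert rep.rms_error_percent == pytest.approx(np.sqrt(np.mean(err**2)))
        assert rep.rmsep == pytest.approx(np.sqrt(np.mean((pred - exp) ** 2)))
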