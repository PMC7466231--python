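"""PLSR calibration: NIPALS, prediction, cross-validation, metrics."""

import numpy as np
import pytest

import hsicolor as h
from hsicolor.plsr import nipals_pls1


def nipals_oracle(Xc, yc, n_components, tol=1e-12, max_iter=500):
    """Independent step-by-step NIPALS (power iteration with deflation),
    written directly from the algorithm definition."""
    X = Xc.copy().astype(float)
    y = yc.copy().astype(float)
    W, P, T, q = [], [], [], []
    for _ in range(n_components):
        w = X.T @ y
        w = w / np.sqrt(w @ w)
        prev = np.zeros_like(w)
        it = 0
        while np.sqrt(np.sum((w - prev) ** 2)) > tol and it < max_iter:
            prev = w
            t = X @ w
            w = X.T @ y / np.sqrt(np.sum((X.T @ y) ** 2))
            it += 1
        t = X @ w
        p = X.T @ t / (t @ t)
        qa = (y @ t) / (t @ t)
        X = X - np.outer(t, p)
        y = y - qa * t
        W.append(w); P.append(p); T.append(t); q.append(qa)
    return (np.array(W).T, np.array(P).T, np.array(T).T, np.array(q))


class TestSplit:
    def test_89_samples_split_59_30(self):
        plan = h.split_samples(89, seed=0)
        assert len(plan.calibration_indices) == 59
        assert len(plan.validation_indices) == 30

    def test_union_covers_all_and_disjoint(self):
        plan = h.split_samples(20, seed=1)
        both = np.concatenate([plan.calibration_indices, plan.validation_indices])
        np.testing.assert_array_equal(np.sort(both), np.arange(20))

    def test_same_seed_identical_plan(self):
        a, b = h.split_samples(50, seed=7), h.split_samples(50, seed=7)
        np.testing.assert_array_equal(a.calibration_indices, b.calibration_indices)

    def test_minimum_size(self):
        plan = h.split_samples(3)
        assert len(plan.calibration_indices) == 2
        assert len(plan.validation_indices) == 1

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_fraction_bounds(self, frac):
        with pytest.raises(ValueError, match="fraction"):
            h.split_samples(10, fraction=frac)


class TestFit:
    def test_noiseless_single_component(self, rng):
        X = rng.normal(size=(20, 6))
        direction = rng.normal(size=6)
        y = X @ direction  # y spanned by X: 6 components fit exactly;
        # one *spectral component*: project X onto the direction
        t = X @ direction / np.linalg.norm(direction)
        X1 = np.outer(t, direction / np.linalg.norm(direction))
        y1 = 2.0 * t + 1.0
        model = h.fit_plsr(X1, y1, 1)
        r2, rmse = h.compute_metrics(y1, h.predict(model, X1))
        assert r2 == pytest.approx(1.0, abs=1e-8)
        assert rmse == pytest.approx(0.0, abs=1e-8)

    def test_full_components_equal_ols(self, rng):
        X = rng.normal(size=(25, 5))
        y = X @ rng.normal(size=5) + 3 + rng.normal(0, 0.2, 25)
        model = h.fit_plsr(X, y, 5)
        A = np.column_stack([np.ones(25), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(h.predict(model, X), A @ beta, atol=1e-8)

    def test_nipals_matches_stepwise_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        W, P, T, q = nipals_pls1(Xc, yc, 3)
        Wo, Po, To, qo = nipals_oracle(Xc, yc, 3)
        np.testing.assert_allclose(W, Wo, atol=1e-10)
        np.testing.assert_allclose(P, Po, atol=1e-10)
        np.testing.assert_allclose(T, To, atol=1e-10)
        np.testing.assert_allclose(q, qo, atol=1e-10)

    def test_matches_sklearn_coefficients(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.5, 30)
        model = h.fit_plsr(X, y, 4)
        sk = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(model.coefficients, sk.coef_.ravel(), atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(5, 10))
        y = rng.normal(size=5)
        with pytest.raises(ValueError, match="n_components"):
            h.fit_plsr(X, y, 5)  # > n-1

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            h.fit_plsr(rng.normal(size=(8, 3)), np.ones(8), 1)

    def test_training_fit_monotone_in_components(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.5, 30)
        rmses = []
        for a in range(1, 8):
            m = h.fit_plsr(X, y, a)
            rmses.append(h.compute_metrics(y, h.predict(m, X))[1])
        assert all(r1 >= r2 - 1e-12 for r1, r2 in zip(rmses, rmses[1:]))

    def test_json_roundtrip(self, small_grid, rng):
        X = h.SpectraMatrix(rng.uniform(0, 1, (12, len(small_grid))), small_grid)
        y = rng.normal(50, 5, 12)
        model = h.fit_plsr(X, y, 3)
        back = h.PLSRModel.from_json(model.to_json())
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.intercept == pytest.approx(model.intercept)
        np.testing.assert_array_equal(back.grid.values, small_grid.values)


class TestPredict:
    def test_reproduces_training_fit(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = h.fit_plsr(X, y, 2)
        np.testing.assert_allclose(h.predict(model, X), model.fitted_values)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = h.fit_plsr(X, y, 2)
        assert h.predict(model, model.x_mean)[0] == pytest.approx(model.y_mean)

    def test_linearity_under_shift(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = h.fit_plsr(X, y, 3)
        shift = rng.normal(size=6)
        delta = h.predict(model, X + shift) - h.predict(model, X)
        np.testing.assert_allclose(delta, shift @ model.coefficients, atol=1e-10)

    def test_band_mismatch_rejected(self, rng):
        model = h.fit_plsr(rng.normal(size=(10, 6)), rng.normal(size=10), 2)
        with pytest.raises(ValueError, match="bands"):
            h.predict(model, rng.normal(size=(3, 5)))


class TestCrossValidation:
    def test_two_latent_factors_found(self, rng):
        n = 30
        T = rng.normal(size=(n, 2))
        loadings = rng.normal(size=(2, 9))
        X = T @ loadings
        y = T @ np.array([2.0, -1.0])
        cv = h.cross_validate(X, y, 5)
        assert cv.optimal_n_components == 2
        assert cv.rmsecv[1] < 1e-6

    def test_rmsecv_nonnegative(self, rng):
        X = rng.normal(size=(15, 5))
        y = rng.normal(size=15)
        cv = h.cross_validate(X, y, 4)
        assert np.all(cv.rmsecv >= 0)

    def test_loo_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(14, 5))
        y = rng.normal(size=14)
        perm = rng.permutation(14)
        a = h.cross_validate(X, y, 3)
        b = h.cross_validate(X[perm], y[perm], 3)
        np.testing.assert_allclose(a.rmsecv, b.rmsecv, atol=1e-10)

    def test_oversized_fold_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="folds exceed"):
            h.cross_validate(X, rng.normal(size=6), 2, scheme="kfold", k=10)

    def test_rmsecv_geq_rmsec_in_expectation(self):
        """With moderate noise, cross-validated error should exceed the
        calibration error for most seeds (majority over 20)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(25, 8))
            y = X @ rng.normal(size=8) + rng.normal(0, 1.0, 25)
            a = 3
            model = h.fit_plsr(X, y, a)
            _, rmsec = h.compute_metrics(y, h.predict(model, X))
            cv = h.cross_validate(X, y, a)
            if cv.rmsecv[a - 1] >= rmsec:
                wins += 1
        assert wins > 10

    def test_infold_pretreatment_refit(self, small_grid, rng):
        """CV with an MSC chain refits the reference inside each fold."""
        X = h.SpectraMatrix(rng.uniform(0.2, 0.8, (14, len(small_grid))), small_grid)
        y = rng.normal(50, 4, 14)
        cv = h.cross_validate(X, y, 3, pretreatment=h.get_pretreatment("msc"))
        assert np.all(np.isfinite(cv.rmsecv))


class TestMetricsAndGrade:
    def test_perfect_prediction(self):
        r2, rmse = h.compute_metrics([1, 2, 3], [1, 2, 3])
        assert (r2, rmse) == (1.0, 0.0)

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = h.compute_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # errors -0.1, 0.1, -0.2, 0.2 → mse 0.025; ss_tot 5
        r2, rmse = h.compute_metrics([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8])
        assert rmse == pytest.approx(np.sqrt(0.025))
        assert r2 == pytest.approx(1 - 0.1 / 5.0)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            h.compute_metrics([2, 2, 2], [1, 2, 3])

    @pytest.mark.parametrize("r2,band", [
        (0.73, "acceptable"), (0.82, "good"), (0.95, "excellent"),
        (0.66, "acceptable"), (0.81, "acceptable"), (0.90, "good"),
        (0.5, "insufficient"), (-1.0, "insufficient"),
    ])
    def test_quality_bands(self, r2, band):
        assert h.grade_model(r2) == band


def test_parameter_recovery_noiseless_sample_set():
    """Noiseless spectra generated linearly from colour: PLSR recovers
    each colour attribute exactly."""
    ss = h.simulate_sample_set(20, noise_sd=0.0, seed=3)
    for j in range(3):
        model = h.fit_plsr(ss.spectra, ss.colours[:, j], 3)
        r2, rmse = h.compute_metrics(ss.colours[:, j], h.predict(model, ss.spectra))
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert rmse < 1e-6


def test_evaluate_model_full_workflow(small_grid):
    rng = np.random.default_rng(0)
    ss = h.simulate_sample_set(20, noise_sd=0.003, seed=4)
    model, metrics = h.evaluate_model(ss.spectra, ss.colours[:, 0],
                                      max_components=6, seed=0,
                                      pretreatment=h.get_pretreatment("snv"))
    assert metrics.r2_c > 0.9
    assert metrics.rmse_gap is not None and metrics.rmse_gap >= 0
    assert model.pretreatment.name == "snv"
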