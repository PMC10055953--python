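"""PLSR/LDA estimators, metrics, cross-validation, split and grid search."""

import numpy as np
import pytest

from visnir.chemometrics import (
    CVConfig,
    PLSRegressionNIPALS,
    ShrinkageLDA,
    cross_validate_config,
    fit_lda,
    fit_plsr,
    fit_report,
    grid_search,
    kfold_cv,
    predict_plsr,
    score_accuracy,
    score_r2,
    score_rmse,
    score_rpd,
    train_val_split,
)
from visnir.preprocess import PreprocessConfig, SGConfig
from visnir.spectra import REFLECTANCE, SpectraDataset, WavelengthGrid


def ols_predict(X, y, X_new):
    """Normal-equations least squares oracle (centered, like PLS at full rank)."""
    Xc = X - X.mean(axis=0)
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
    return (X_new - X.mean(axis=0)) @ beta + y.mean()


class TestPLSR:
    def test_rank_one_exact_fit_with_single_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=12)
        X = np.outer(t, np.array([1.0, -2.0, 0.5]))
        y = 3.0 * t + 1.0
        model = fit_plsr(X, y, 1)
        assert score_r2(y, model.predict(X)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(6, 21), rng.integers(3, 9)
        if p >= n:
            p = n - 2
        X = rng.normal(size=(int(n), int(p)))
        y = rng.normal(size=int(n))
        model = fit_plsr(X, y, int(p))
        np.testing.assert_allclose(model.predict(X), ols_predict(X, y, X),
                                   atol=1e-8)

    def test_training_r2_monotone_in_components(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 10))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(size=30) * 0.5
        r2 = [score_r2(y, fit_plsr(X, y, k).predict(X)) for k in range(1, 9)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_zero_components_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError):
            fit_plsr(X, X[:, 0], 0)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_plsr(np.ones((6, 3)), np.arange(6.0), 1)

    def test_rank_deficient_request_stops_early_with_warning(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=5))  # rank 1
        y = 2 * t
        with pytest.warns(UserWarning, match="stopped early"):
            model = fit_plsr(X, y, 4)
        assert model.n_components_ < 4

    def test_mean_row_predicts_mean_target(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = fit_plsr(X, y, 3)
        assert predict_plsr(model, X.mean(axis=0)[None, :])[0] == \
            pytest.approx(y.mean())

    def test_predict_shape_mismatch_rejected(self):
        model = fit_plsr(np.random.default_rng(0).normal(size=(8, 4)),
                         np.arange(8.0), 2)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((3, 5)))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_reference_pls_implementation(self, seed):
        """Cross-library oracle: sklearn's PLSRegression (scale=False) is the
        same NIPALS/PLS1 algorithm and must agree to 1e-6."""
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        ours = fit_plsr(X, y, 4).predict(X)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-6)


class TestLDA:
    def _two_blobs(self, sep, n=30, seed=0):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(size=(n, 5))
        X1 = rng.normal(size=(n, 5)) + np.array([sep, 0, 0, 0, 0])
        return np.vstack([X0, X1]), np.array([0] * n + [1] * n)

    def test_separated_classes_training_accuracy_one(self):
        X, y = self._two_blobs(8.0)
        model = fit_lda(X, y)
        assert score_accuracy(y, model.predict(X)) == 1.0

    def test_component_count_bounded_by_classes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 8))
        y = np.repeat(np.arange(6), 10)
        model = fit_lda(X, y)
        assert model.scalings_.shape[1] == 5
        with pytest.raises(ValueError):
            fit_lda(X, y, n_components=6)

    def test_identical_means_accuracy_near_chance(self):
        rng = np.random.default_rng(2)
        accs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(120, 4))
            y = np.repeat(np.arange(4), 30)
            model = fit_lda(X, y)
            accs.append(score_accuracy(y, model.predict(X)))
        # chance level 0.25; training optimism allows some headroom
        assert 0.2 < np.mean(accs) < 0.45

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match=">= 2"):
            fit_lda(X, np.array([0, 0, 1, 1, 2]))

    def test_deterministic_sign_convention(self):
        X, y = self._two_blobs(4.0, seed=5)
        a = fit_lda(X, y)
        b = fit_lda(X, y)
        np.testing.assert_array_equal(a.scalings_, b.scalings_)
        j = np.argmax(np.abs(a.scalings_[:, 0]))
        assert a.scalings_[j, 0] > 0


class TestMetrics:
    def test_r2_hand_values(self):
        assert score_r2([1, 2, 3], [1, 2, 3]) == 1.0
        y = np.array([1.0, 2.0, 3.0])
        assert score_r2(y, np.full(3, y.mean())) == 0.0
        assert score_r2([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_r2_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            score_r2([2, 2, 2], [1, 2, 3])

    def test_rmse_hand_values(self):
        assert score_rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert score_rmse([0, 0, 0], [0, -1, 1]) == pytest.approx(np.sqrt(2 / 3))
        y = np.array([1.0, 5.0, 9.0])
        assert score_rmse(y, y + 0.7) == pytest.approx(0.7)

    def test_rpd_hand_values(self):
        # sd(y) = 2 (population), rmse = 1 -> RPD = 2
        y = np.array([-2.0, 2.0, -2.0, 2.0])
        y_hat = y + np.array([1.0, -1.0, 1.0, -1.0])
        assert score_rpd(y, y_hat) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            score_rpd(y, y)

    def test_rpd_of_null_model_near_one(self):
        y = np.random.default_rng(0).normal(size=2000)
        assert score_rpd(y, np.full_like(y, y.mean())) == pytest.approx(1.0)

    def test_accuracy_hand_values(self):
        assert score_accuracy([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
        assert score_accuracy([1, 2, 3, 4], [1, 2, 0, 0]) == 0.5
        assert score_accuracy([1, 2], [3, 4]) == 0.0
        with pytest.raises(ValueError):
            score_accuracy([], [])


class TestCrossValidation:
    def test_folds_partition_exactly_once(self):
        cv = CVConfig(k=7, shuffle=True, seed=3)
        folds = cv.folds(40)
        all_test = np.sort(np.concatenate([t for _, t in folds]))
        np.testing.assert_array_equal(all_test, np.arange(40))
        for train, test in folds:
            assert np.intersect1d(train, test).size == 0

    def test_leave_one_out_on_noiseless_linear_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 7.0
        res = kfold_cv(X, y, PLSRegressionNIPALS(4), CVConfig(k=20), "regression")
        assert res.rmsecv < 1e-8

    def test_matches_explicit_fold_loop(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        y = X[:, 0] + rng.normal(size=30) * 0.3
        cv = CVConfig(k=5, shuffle=True, seed=9)
        res = kfold_cv(X, y, PLSRegressionNIPALS(3), cv, "regression")
        # independent loop oracle on the same fold definitions
        oof = np.empty(30)
        for train, test in cv.folds(30):
            m = PLSRegressionNIPALS(3).fit(X[train], y[train])
            oof[test] = m.predict(X[test])
        np.testing.assert_allclose(res.predictions, oof)
        assert res.rmsecv == pytest.approx(score_rmse(y, oof))

    def test_classification_fold_losing_class_errors(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="fold"):
            kfold_cv(X, y, ShrinkageLDA(), CVConfig(k=4, shuffle=False),
                     "classification")


class TestTrainValSplit:
    def _ds(self, n):
        wl = np.linspace(500.0, 900.0, 20)
        rng = np.random.default_rng(0)
        return SpectraDataset(WavelengthGrid(wl),
                              rng.uniform(0.2, 0.8, size=(n, 20)), REFLECTANCE,
                              [f"s{i}" for i in range(n)],
                              brix=rng.uniform(7, 20, n))

    def test_sizes_and_partition(self):
        train, val = train_val_split(self._ds(10), 0.8, seed=1)
        assert train.n_samples == 8 and val.n_samples == 2
        assert set(train.sample_ids) | set(val.sample_ids) == \
            set(self._ds(10).sample_ids)
        assert not set(train.sample_ids) & set(val.sample_ids)

    def test_deterministic_under_seed(self):
        a1, _ = train_val_split(self._ds(23), seed=5)
        a2, _ = train_val_split(self._ds(23), seed=5)
        assert a1.sample_ids == a2.sample_ids

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            train_val_split(self._ds(4))


def _linear_dataset(n=40, noise=0.0, seed=0):
    """Reflectance dataset whose Brix is exactly linear in one band."""
    rng = np.random.default_rng(seed)
    wl = np.linspace(445.0, 1061.0, 100)
    brix = rng.uniform(7.0, 20.0, n)
    rows = []
    for b in brix:
        A = 0.3 + 0.012 * b * np.exp(-((wl - 969.0) ** 2) / (2 * 28 ** 2))
        rows.append(np.power(10.0, -(A + rng.normal(size=100) * noise)))
    return SpectraDataset(WavelengthGrid(wl), np.vstack(rows), REFLECTANCE,
                          [f"s{i}" for i in range(n)], brix=brix)


class TestFitReport:
    def test_noiseless_linear_data_identity_line(self):
        ds = _linear_dataset(noise=0.0)
        train, val = train_val_split(ds, seed=0)
        res = fit_report(train, val, PreprocessConfig(), {"n_components": 2},
                         CVConfig(k=5, seed=0), "regression")
        assert res.slope == pytest.approx(1.0, abs=1e-3)
        assert res.intercept == pytest.approx(0.0, abs=2e-2)
        assert res.bias == pytest.approx(0.0, abs=1e-3)
        assert res.r2p == pytest.approx(1.0, abs=1e-4)

    def test_constant_shift_appears_as_bias(self):
        y = np.linspace(5.0, 20.0, 50)
        y_hat = y + 0.5
        slope, intercept = np.polyfit(y, y_hat, 1)
        assert slope == pytest.approx(1.0)
        assert float(np.mean(y_hat - y)) == pytest.approx(0.5)

    def test_report_carries_standard_score_set(self):
        ds = _linear_dataset(noise=0.002, seed=2)
        train, val = train_val_split(ds, seed=0)
        res = fit_report(train, val, PreprocessConfig(), {"n_components": 3},
                         CVConfig(k=5, seed=0), "regression")
        d = res.to_dict()
        for key in ("n_components", "r2c", "rmsec", "r2cv", "rmsecv", "r2p",
                    "rmsep", "rpd"):
            assert d[key] is not None and np.isfinite(d[key])


class TestGridSearch:
    def test_single_point_grid_returns_it(self):
        ds = _linear_dataset(noise=0.002, seed=1)
        gs = grid_search(ds, [PreprocessConfig()], [{"n_components": 2}],
                         CVConfig(k=5, seed=0), "regression")
        assert gs.best_params == {"n_components": 2}
        assert gs.best_score == gs.best_cv.rmsecv

    def test_selection_minimises_rmsecv(self):
        ds = _linear_dataset(noise=0.002, seed=1)
        gs = grid_search(ds, [PreprocessConfig()],
                         [{"n_components": k} for k in (1, 2, 4)],
                         CVConfig(k=5, seed=0), "regression")
        scores = {tuple(e["params"].items()): e["rmsecv"] for e in gs.audit}
        assert gs.best_score == min(scores.values())

    def test_all_failing_configs_aggregate_error(self):
        ds = _linear_dataset(n=10)
        with pytest.raises(RuntimeError, match="failed"):
            grid_search(ds, [PreprocessConfig()], [{"n_components": 99}],
                        CVConfig(k=5, seed=0), "regression")

    def test_derivative_selected_under_smooth_baseline_scatter(self):
        """When the compositional signal must be read from band slopes
        (smooth per-sample baselines dominate), the grid picks a derivative
        configuration."""
        from visnir.instrument import MockSpectrometerSpec
        from visnir.synthetic import GeneratorConfig, generate_dataset

        cfg = GeneratorConfig(scatter_baseline_sd=0.10, noise_sd=0.002,
                              n_samples=80)
        data = generate_dataset(cfg, {"vis": MockSpectrometerSpec.default_vis()},
                                seed=22)
        pgrid = [PreprocessConfig(),
                 PreprocessConfig(derivative=SGConfig(11, 2, 1))]
        gs = grid_search(data["vis"], pgrid,
                         [{"n_components": k} for k in range(1, 13)],
                         CVConfig(k=10, seed=0), "regression")
        assert gs.best_config.derivative is not None
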