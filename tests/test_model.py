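"""SIMPLS estimator: oracle equivalences, conventions, serialization; LR baseline."""

import numpy as np
import pytest

from capsense.dataio import AlignedDataset, spline_align
from capsense.errors import DegenerateDataError, InsufficientDataError, RankError, SchemaError
from capsense.model import (LinearModel, PLSModel, fit_linear_baseline, fit_pls,
                            predict_linear, predict_vcc)
from capsense.preprocess import FrequencyWindow, ScalingParams
from capsense.simulate import CultureParams, simulate_run

from conftest import EXACT_SAMPLING, NOISELESS, clean_clone, short_culture


def random_dataset(n, p, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 100, (n, p))
    b = rng.standard_normal(p)
    y = X @ b + 5.0 + noise * rng.standard_normal(n)
    return AlignedDataset(times=np.arange(n, dtype=float), X=X, y=y), b


class TestSimpls:
    def test_exact_linear_recovery(self):
        ds, b = random_dataset(30, 3, seed=0)
        model = fit_pls(ds, window=FrequencyWindow.upto(3), n_components=3)
        assert np.allclose(model.coefficients, b, rtol=1e-8)
        y_hat = predict_vcc(model, ds.X)
        assert np.allclose(y_hat, ds.y, rtol=1e-8)

    @pytest.mark.parametrize("scaling_mode", ["mean_center", "standardize"])
    def test_full_rank_equals_least_squares(self, scaling_mode):
        """At n_components = rank, SIMPLS reproduces OLS on the same columns."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(8, 40))
            p = int(rng.integers(2, 7))
            X = rng.standard_normal((n, p)) * rng.uniform(0.5, 20, p)
            y = rng.standard_normal(n)
            ds = AlignedDataset(times=np.arange(n, dtype=float), X=X, y=y)
            model = fit_pls(ds, window=FrequencyWindow.upto(p),
                            scaling_mode=scaling_mode, n_components=p)
            Xc = np.column_stack([X, np.ones(n)])
            beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
            y_ols = Xc @ beta
            assert np.allclose(predict_vcc(model, X), y_ols, rtol=1e-8, atol=1e-8)

    def test_agrees_with_independent_nipals(self):
        """Cross-implementation check against scikit-learn's NIPALS PLS."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(7)
        for trial in range(25):
            n, p, a = 50, 10, 3
            X = rng.uniform(0, 10, (n, p))
            y = X @ rng.standard_normal(p) + rng.standard_normal(n)
            ds = AlignedDataset(times=np.arange(n, dtype=float), X=X, y=y)
            model = fit_pls(ds, window=FrequencyWindow.upto(p), n_components=a)
            sk = PLSRegression(n_components=a, scale=False).fit(X, y)
            assert np.allclose(predict_vcc(model, X), sk.predict(X).ravel(),
                               rtol=1e-6, atol=1e-6)

    def test_narrow_window_reduces_components(self):
        ds, _ = random_dataset(20, 2, seed=1, noise=0.1)
        model = fit_pls(ds, window=FrequencyWindow.upto(2), n_components=3)
        assert model.n_components == 2
        model1 = fit_pls(ds, window=FrequencyWindow.upto(1), n_components=3)
        assert model1.n_components == 1

    def test_component_nesting_training_rmse(self):
        ds, _ = random_dataset(60, 6, seed=3, noise=20.0)
        rmses = []
        for a in range(1, 6):
            m = fit_pls(ds, window=FrequencyWindow.upto(6), n_components=a)
            resid = ds.y - predict_vcc(m, ds.X)
            rmses.append(float(np.sqrt(np.mean(resid**2))))
        assert all(r2 <= r1 + 1e-9 for r1, r2 in zip(rmses, rmses[1:]))

    def test_raw_coefficients_equal_scaled_space_path(self):
        """Back-mapped coefficients reproduce scale-then-predict to 1e-9."""
        from capsense.preprocess import apply_scaling

        ds, _ = random_dataset(40, 5, seed=4, noise=5.0)
        model = fit_pls(ds, window=FrequencyWindow.upto(5),
                        scaling_mode="standardize", n_components=3)
        raw = predict_vcc(model, ds.X)
        Xs = apply_scaling(ds.X, model.scaling)
        coef_scaled = np.asarray(model.coefficients) * np.asarray(model.scaling.sds)
        via_scaled = Xs @ coef_scaled + (model.intercept
                                         + np.asarray(model.coefficients)
                                         @ np.asarray(model.scaling.means))
        assert np.allclose(raw, via_scaled, rtol=1e-9, atol=1e-9)

    def test_rank_error_on_collinear_columns(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 10, (20, 1))
        X = np.hstack([X, 2 * X, 3 * X])
        ds = AlignedDataset(times=np.arange(20.0), X=X, y=rng.standard_normal(20))
        with pytest.raises(RankError):
            fit_pls(ds, window=FrequencyWindow.upto(3), n_components=3)

    def test_too_few_rows(self):
        ds, _ = random_dataset(3, 5, seed=6)
        with pytest.raises(InsufficientDataError):
            fit_pls(ds, window=FrequencyWindow.upto(5), n_components=3)

    def test_missing_window_column(self):
        ds, _ = random_dataset(20, 4, seed=7)
        model = fit_pls(ds, window=FrequencyWindow.upto(4), n_components=2)
        with pytest.raises(SchemaError):
            predict_vcc(model, ds.X[:, :2])


class TestPredictionEquation:
    def test_unit_exemplar_arithmetic(self):
        """One channel at 100 pF/cm, coefficient -1.5, intercept 200 -> 50."""
        model = PLSModel(
            frequency_window=FrequencyWindow.upto(1),
            scaling=ScalingParams("mean_center", (0.0,), (1.0,)),
            n_components=1,
            coefficients=(-1.5,),
            intercept=200.0,
        )
        assert predict_vcc(model, [[100.0]])[0] == pytest.approx(50.0)

    def test_zero_coefficients_return_intercept(self):
        model = PLSModel(
            frequency_window=FrequencyWindow.upto(2),
            scaling=ScalingParams("mean_center", (0.0, 0.0), (1.0, 1.0)),
            n_components=2,
            coefficients=(0.0, 0.0),
            intercept=42.0,
        )
        assert np.allclose(predict_vcc(model, np.ones((5, 2))), 42.0)

    def test_negative_estimates_not_clipped(self):
        neg = PLSModel(
            frequency_window=FrequencyWindow.upto(2),
            scaling=ScalingParams("mean_center", (0.0, 0.0), (1.0, 1.0)),
            n_components=2,
            coefficients=(-1.0, 0.0),
            intercept=0.0,
        )
        assert predict_vcc(neg, [[10.0, 0.0]])[0] == -10.0


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, tmp_path):
        ds, _ = random_dataset(30, 5, seed=9, noise=3.0)
        model = fit_pls(ds, window=FrequencyWindow.upto(5),
                        scaling_mode="standardize", n_components=3)
        path = model.save(tmp_path / "model.json")
        back = PLSModel.load(path)
        assert back == model
        assert back.coefficients == model.coefficients  # exact floats, not approx

    def test_linear_model_round_trip(self, tmp_path):
        lm = LinearModel(working_frequency=6, reference_frequency=17,
                         slope=1.2345678901234567, intercept=-0.5, r_squared=0.987)
        back = LinearModel.load(lm.save(tmp_path / "lm.json"))
        assert back == lm


class TestLinearBaseline:
    def test_exact_dual_mode_fit(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 50, (30, 17))
        y = 2.0 * (X[:, 5] - X[:, 16]) + 1.0
        ds = AlignedDataset(times=np.arange(30.0), X=X, y=y)
        lm = fit_linear_baseline(ds, calibration_phase="whole_run")
        assert lm.working_frequency == 6  # grid frequency nearest 1 MHz
        assert lm.reference_frequency == 17
        assert lm.slope == pytest.approx(2.0, rel=1e-9)
        assert lm.intercept == pytest.approx(1.0, abs=1e-7)
        assert np.allclose(predict_linear(lm, X), y, rtol=1e-9)

    def test_exponential_phase_clean_run_correlates_excellently(self):
        srun = simulate_run(clean_clone(), CultureParams(), NOISELESS, EXACT_SAMPLING, seed=2)
        lm = fit_linear_baseline(spline_align(srun.to_fermentation_run("c")),
                                 calibration_phase="exponential_only")
        assert lm.r_squared >= 0.99

    def test_overestimates_after_peak_on_debris_heavy_run(self, debris_heavy_run):
        run = debris_heavy_run.to_fermentation_run("d")
        lm = fit_linear_baseline(spline_align(run), calibration_phase="exponential_only")
        y_hat = predict_linear(lm, run.spectra)
        truth = debris_heavy_run.ground_truth_vcc
        late = run.times_online > 260.0
        assert np.mean(y_hat[late] - truth[late]) > 0.5 * np.mean(truth[late])

    def test_constant_regressor_rejected(self):
        X = np.ones((10, 17))
        ds = AlignedDataset(times=np.arange(10.0), X=X, y=np.arange(10.0))
        with pytest.raises(DegenerateDataError):
            fit_linear_baseline(ds, calibration_phase="whole_run")

    def test_bad_phase_name(self):
        ds, _ = random_dataset(10, 17, seed=1)
        with pytest.raises(ValueError):
            fit_linear_baseline(ds, calibration_phase="decline_only")
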