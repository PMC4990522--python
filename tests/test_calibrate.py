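import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scatterbmd.calibrate import (
    CalibrationModel,
    classify_bmd,
    estimate_density,
    fit_calibration,
    load_model,
    midpoint_cutoff,
    save_model,
)


class TestFitCalibration:
    def test_exact_line_through_two_points(self):
        model = fit_calibration([(0.0, 10.0), (100.0, 20.0)])
        assert model.slope == pytest.approx(0.1)
        assert model.intercept == pytest.approx(10.0)
        assert model.residual_sd == 0.0

    def test_perfect_fit_has_zero_residual(self):
        pairs = [(d, 2.0 * d + 5.0) for d in (0, 50, 100, 200)]
        model = fit_calibration(pairs)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(5.0)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_recovery_to_machine_precision(self):
        rng = np.random.default_rng(4)
        slope, intercept = -3.25, 417.0
        d = rng.uniform(0, 300, size=20)
        model = fit_calibration([(x, slope * x + intercept) for x in d])
        assert model.slope == pytest.approx(slope, rel=1e-12)
        assert model.intercept == pytest.approx(intercept, rel=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(50.0, 1.0), (50.0, 2.0), (50.0, 3.0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(0.0, 1.0)])


class TestEstimateDensity:
    def test_exact_inversion(self):
        model = CalibrationModel(slope=0.1, intercept=10.0, residual_sd=0.0, n_points=2)
        assert estimate_density(20.0, model).value == pytest.approx(100.0)

    def test_count_at_intercept_maps_to_zero(self):
        model = CalibrationModel(slope=0.1, intercept=10.0, residual_sd=0.5, n_points=3)
        est = estimate_density(10.0, model)
        assert est.value == pytest.approx(0.0)
        assert est.sd == pytest.approx(5.0)

    def test_negative_estimates_flagged_not_clipped(self):
        model = CalibrationModel(slope=2.0, intercept=100.0, residual_sd=0.0, n_points=2)
        est = estimate_density(50.0, model)
        assert est.value == pytest.approx(-25.0)
        assert est.negative

    def test_zero_slope_unidentifiable(self):
        model = CalibrationModel(slope=0.0, intercept=10.0, residual_sd=0.0, n_points=2)
        with pytest.raises(ValueError):
            estimate_density(20.0, model)

    @settings(derandomize=True)
    @given(
        st.floats(0.01, 100), st.floats(-1e3, 1e3), st.floats(-500, 500)
    )
    def test_inverse_of_prediction_is_identity(self, slope, intercept, density):
        model = CalibrationModel(
            slope=slope, intercept=intercept, residual_sd=0.0, n_points=2
        )
        est = estimate_density(model.predict_count(density), model)
        assert est.value == pytest.approx(density, abs=1e-6)


class TestClassification:
    def test_below_cutoff_is_low_bmd(self):
        assert classify_bmd(100.0, 200.0) == "low_bmd"

    def test_boundary_assigned_to_normal(self):
        assert classify_bmd(200.0, 200.0) == "normal"

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify_bmd(100.0, 0.0)

    def test_midpoint_cutoff(self):
        assert midpoint_cutoff(2332.0, 5572.0) == pytest.approx(3952.0)


class TestPersistence:
    def test_yaml_round_trip(self, tmp_path):
        model = CalibrationModel(slope=1.5, intercept=-3.0, residual_sd=0.7, n_points=4)
        path = tmp_path / "model.yaml"
        save_model(model, path)
        assert load_model(path) == model
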