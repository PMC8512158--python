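"""Calibration transfer function: fit, evaluation, inversion, bench numbers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myobelt.calibration import (BELT_CURVE, CalibrationCurve, CalibrationPoint,
                                 capacitance_to_length, fit_calibration,
                                 goodness_of_fit, hysteresis_index,
                                 length_to_capacitance, read_calibration_csv,
                                 sensor_characterization, write_calibration_csv,
                                 save_curve_json, load_curve_json)
from myobelt.errors import DegenerateDesignError, ValidationError


def points_on(curve, capacitances):
    return [CalibrationPoint(c, capacitance_to_length(curve, c)) for c in capacitances]


class TestTransferFunction:
    @pytest.mark.parametrize("cap, expected_mm", [(500.0, 111.4672), (465.0, 96.5562)])
    def test_forward_evaluation(self, belt_curve, cap, expected_mm):
        assert capacitance_to_length(belt_curve, cap) == pytest.approx(expected_mm, abs=5e-5)

    def test_constant_curve_returns_intercept(self):
        curve = CalibrationCurve(a2=0.0, a1=1e-9, a0=42.0, valid_range=(1.0, 2.0))
        assert capacitance_to_length(curve, 1.5) == pytest.approx(42.0)

    def test_nonfinite_capacitance_rejected(self, belt_curve):
        with pytest.raises(ValidationError):
            capacitance_to_length(belt_curve, np.nan)

    def test_out_of_range_warns_not_fails(self, belt_curve):
        with pytest.warns(UserWarning, match="outside the calibration range"):
            capacitance_to_length(belt_curve, 700.0)

    def test_strictly_increasing_on_valid_range(self, belt_curve):
        C = np.linspace(*belt_curve.valid_range, 500)
        L = capacitance_to_length(belt_curve, C)
        assert np.all(np.diff(L) > 0)

    def test_non_monotone_range_rejected(self):
        # vertex of the belt curve is ~387 nF; a range straddling it is invalid
        with pytest.raises(ValidationError):
            CalibrationCurve(a2=0.00223, a1=-1.72592, a0=416.9272, valid_range=(300.0, 606.0))


class TestInverse:
    def test_known_inversion(self, belt_curve):
        assert length_to_capacitance(belt_curve, 111.4672) == pytest.approx(500.0, abs=1e-6)

    def test_round_trip_across_operating_range(self, belt_curve):
        C = np.linspace(400.0, 700.0, 301)
        with np.errstate(all="raise"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                back = length_to_capacitance(belt_curve, capacitance_to_length(belt_curve, C))
        assert np.max(np.abs(back - C)) < 1e-9

    def test_length_below_vertex_has_no_solution(self, belt_curve):
        with pytest.raises(ValidationError, match="below the curve minimum"):
            length_to_capacitance(belt_curve, 0.0)


class TestFit:
    def test_three_exact_points_interpolate(self, belt_curve):
        pts = points_on(belt_curve, [465.0, 530.0, 606.0])
        fitted = fit_calibration(pts)
        assert fitted.a2 == pytest.approx(belt_curve.a2, rel=1e-9)
        assert fitted.a1 == pytest.approx(belt_curve.a1, rel=1e-9)
        assert fitted.a0 == pytest.approx(belt_curve.a0, rel=1e-9)

    def test_symmetric_perturbations_recovered(self, belt_curve):
        # paired +-delta residuals at paired abscissae cancel in the normal equations
        caps = [470.0, 470.0, 520.0, 520.0, 590.0, 590.0]
        delta = 0.5
        pts = [CalibrationPoint(c, capacitance_to_length(belt_curve, c) + s * delta)
               for c, s in zip(caps, [1, -1, 1, -1, 1, -1])]
        fitted = fit_calibration(pts)
        C = np.linspace(470, 590, 50)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            err = np.abs(capacitance_to_length(fitted, C) - capacitance_to_length(belt_curve, C))
        assert np.max(err) < delta

    def test_degenerate_design_raises(self):
        pts = [CalibrationPoint(500.0, L) for L in (100.0, 110.0, 120.0)]
        with pytest.raises(DegenerateDesignError):
            fit_calibration(pts)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_normal_equations_oracle(self, seed):
        # sensor-like designs: increasing quadratic plus measurement noise
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        C = rng.uniform(420.0, 650.0, n)
        C[:3] = [430.0, 500.0, 640.0]  # guarantee 3 distinct abscissae
        a2 = rng.uniform(0.001, 0.004)
        vertex = rng.uniform(200.0, 400.0)
        a1 = -2.0 * a2 * vertex
        a0 = rng.uniform(200.0, 500.0)
        L = a2 * C ** 2 + a1 * C + a0 + rng.normal(0.0, 1.0, n)
        L += max(0.0, 1.0 - L.min())  # lengths must be physical (> 0)
        pts = [CalibrationPoint(c, l) for c, l in zip(C, L)]
        fitted = fit_calibration(pts)
        X = np.column_stack([C ** 2, C, np.ones(n)])
        oracle = np.linalg.solve(X.T @ X, X.T @ L)
        got = np.array([fitted.a2, fitted.a1, fitted.a0])
        assert np.allclose(got, oracle, rtol=1e-8, atol=1e-10)


class TestGoodnessOfFit:
    def test_exact_points_give_100_percent(self, belt_curve):
        pts = points_on(belt_curve, [465.0, 500.0, 550.0, 606.0])
        assert goodness_of_fit(pts, belt_curve) == pytest.approx(100.0)

    def test_mean_predictor_gives_zero_percent(self):
        lengths = [90.0, 110.0, 130.0, 150.0]
        curve = CalibrationCurve(0.0, 1e-9, float(np.mean(lengths)), valid_range=(1.0, 4.0))
        pts = [CalibrationPoint(c, l) for c, l in zip([1.0, 2.0, 3.0, 4.0], lengths)]
        assert goodness_of_fit(pts, curve) == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_ss_ratio(self, belt_curve):
        caps = [470.0, 510.0, 550.0, 590.0]
        pts = points_on(belt_curve, caps)
        # displace one point by exactly 1 mm
        pts[2] = CalibrationPoint(550.0, pts[2].length_mm + 1.0)
        lengths = np.array([p.length_mm for p in pts])
        ss_tot = np.sum((lengths - lengths.mean()) ** 2)
        expected = 100.0 * (1.0 - 1.0 / ss_tot)  # SS_res is exactly 1 mm^2
        assert goodness_of_fit(pts, belt_curve) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self, belt_curve):
        pts = [CalibrationPoint(c, 100.0) for c in (465.0, 500.0)]
        with pytest.raises(ValidationError):
            goodness_of_fit(pts, belt_curve)


class TestHysteresis:
    def test_identical_sweeps_zero(self, belt_curve):
        sweep = points_on(belt_curve, np.linspace(465, 606, 15))
        assert hysteresis_index(sweep, sweep) == 0.0

    def test_constant_offset_detected(self, belt_curve):
        fwd = points_on(belt_curve, np.linspace(465, 606, 15))
        bwd = [CalibrationPoint(p.capacitance_nF + 2.0, p.length_mm) for p in fwd]
        assert hysteresis_index(fwd, bwd) == pytest.approx(2.0, rel=1e-9)

    def test_interleaved_sample_positions_small(self, belt_curve):
        fwd = points_on(belt_curve, np.linspace(465, 606, 30))
        bwd = points_on(belt_curve, np.linspace(467, 604, 29))  # offset abscissae
        # zero physical hysteresis; only linear-interpolation error remains
        assert hysteresis_index(fwd, bwd) < 0.05

    def test_non_overlapping_ranges_rejected(self, belt_curve):
        fwd = points_on(belt_curve, [465.0, 500.0])
        bwd = points_on(belt_curve, [550.0, 606.0])
        with pytest.raises(ValidationError, match="overlap"):
            hysteresis_index(fwd, bwd)


class TestSensorCharacterization:
    def test_bench_numbers(self):
        out = sensor_characterization(95.0, 200.0, 18.0, 15.0, 150.0)
        assert out["elongation_percent"] == pytest.approx(110.0, abs=0.6)
        assert out["areal_density_mg_per_mm2"] == pytest.approx(8.0e-3, rel=1e-12)

    def test_no_stretch_is_zero_elongation(self):
        out = sensor_characterization(95.0, 95.0, 18.0, 15.0, 150.0)
        assert out["elongation_percent"] == 0.0

    @pytest.mark.parametrize("kwargs", [
        dict(L0_mm=0.0, L1_mm=200.0, added_mass_mg=18, flock_width_mm=15, flock_depth_mm=150),
        dict(L0_mm=95.0, L1_mm=200.0, added_mass_mg=18, flock_width_mm=0, flock_depth_mm=150),
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            sensor_characterization(**kwargs)


def test_csv_and_json_round_trip(tmp_path, belt_curve):
    pts = points_on(belt_curve, [465.0, 530.0, 606.0])
    write_calibration_csv(pts, tmp_path / "sweep.csv")
    back = read_calibration_csv(tmp_path / "sweep.csv")
    assert back == pts
    save_curve_json(belt_curve, tmp_path / "curve.json")
    loaded = load_curve_json(tmp_path / "curve.json")
    assert loaded == belt_curve
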