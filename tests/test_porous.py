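"""Porous resistance model: calibration, prediction, scaling, momentum sink."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vortislot as v
from vortislot.porous import (
    CALIBRATION_FLUID,
    CalibrationError,
    PressureDropSample,
    momentum_sink,
    read_samples_csv,
    write_samples_csv,
)


class TestCalibration:
    def test_two_point_calibration_recovers_printed_coefficients(self, calibrated_spec):
        # 29.3 Pa at 0.1 m/s and 293.6 Pa at 0.5 m/s across a 50 um layer
        assert calibrated_spec.alpha_n == pytest.approx(2.3468e-10, rel=1e-4)
        assert calibrated_spec.c2 == pytest.approx(29473.0, rel=1e-4)

    def test_linear_samples_force_pure_darcy_fit(self):
        fluid = v.FluidProperties(density=998.2, viscosity=1.0)
        samples = [PressureDropSample(1.0, 1.0), PressureDropSample(2.0, 2.0)]
        spec = v.calibrate_porous_parameters(samples, fluid, dm=1.0)
        assert spec.c2 == pytest.approx(0.0, abs=1e-12)
        assert spec.alpha_n == pytest.approx(1.0, rel=1e-12)

    def test_duplicate_velocities_raise_singular_error(self):
        samples = [PressureDropSample(0.1, 10.0), PressureDropSample(0.1, 12.0)]
        with pytest.raises(CalibrationError, match="distinct velocities"):
            v.calibrate_porous_parameters(samples)

    def test_non_physical_fit_reports_raw_values(self):
        # decreasing pressure drop with velocity => negative Darcy slope
        samples = [PressureDropSample(0.1, 100.0), PressureDropSample(0.5, 10.0)]
        with pytest.raises(CalibrationError, match="non-physical"):
            v.calibrate_porous_parameters(samples)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(1e-12, 1e-8),
        c2=st.floats(1e2, 1e6),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_recovers_random_coefficients(self, alpha, c2, seed):
        """Exact samples generated from (alpha*, C2*) refit to 10 digits.

        When one loss term dominates the other by many orders of magnitude
        the minor coefficient unavoidably loses digits to floating point, so
        the bound on each coefficient is scaled by that term ratio.
        """
        rng = np.random.default_rng(seed)
        dm = 50e-6
        true = v.PorousLayerSpec(alpha_n=alpha, c2=c2, dm=dm)
        vs = np.sort(rng.uniform(0.05, 1.0, size=5))
        samples = [
            PressureDropSample(vv, -v.predict_pressure_jump(vv, true))
            for vv in vs
        ]
        fit = v.calibrate_porous_parameters(samples, dm=dm)
        visc = CALIBRATION_FLUID.viscosity / alpha * np.median(vs)
        inert = c2 * CALIBRATION_FLUID.density / 2 * np.median(vs) ** 2
        eps = np.finfo(float).eps
        tol_a = max(1e-10, 100 * eps * inert / visc)
        tol_c = max(1e-10, 100 * eps * visc / inert)
        assert fit.alpha_n == pytest.approx(alpha, rel=tol_a)
        assert fit.c2 == pytest.approx(c2, rel=tol_c)


class TestPrediction:
    @pytest.mark.parametrize(
        "velocity,expected,rel",
        [
            (0.183, -64.8, 2e-3),   # out-of-sample prediction
            (0.0, 0.0, None),
            (0.1, -29.3, 2e-3),     # calibration point reproduced
            (0.5, -293.6, 2e-3),
        ],
    )
    def test_pressure_jump_values(self, calibrated_spec, velocity, expected, rel):
        got = v.predict_pressure_jump(velocity, calibrated_spec)
        if rel is None:
            assert got == 0.0
        else:
            assert got == pytest.approx(expected, rel=rel)

    def test_jump_strictly_decreasing_in_velocity(self, calibrated_spec):
        vs = np.linspace(0.01, 1.0, 40)
        jumps = [v.predict_pressure_jump(x, calibrated_spec) for x in vs]
        assert np.all(np.diff(jumps) < 0)

    def test_quadratic_to_linear_term_ratio(self, calibrated_spec):
        """inertial/viscous contribution ratio = (C2 rho alpha / 2 mu) * v."""
        s, f = calibrated_spec, CALIBRATION_FLUID
        for vel in (0.05, 0.183, 0.7):
            linear = f.viscosity / s.alpha_n * vel * s.dm
            quad = -v.predict_pressure_jump(vel, s) - linear
            expected = s.c2 * f.density * s.alpha_n / (2 * f.viscosity) * vel
            assert quad / linear == pytest.approx(expected, rel=1e-9)


class TestScenarios:
    def test_half_resistance_matches_printed_coefficients(self, calibrated_spec):
        half = v.scale_resistance(calibrated_spec, v.SCENARIOS["half"])
        assert half.viscous_resistance_n == pytest.approx(2.13e9, rel=5e-3)
        assert half.viscous_resistance_t == pytest.approx(5e9, rel=1e-9)
        assert half.c2 == pytest.approx(14737.0, rel=1e-4)

    def test_original_is_identity(self, calibrated_spec):
        assert v.scale_resistance(calibrated_spec, v.SCENARIOS["original"]) == calibrated_spec

    def test_none_returns_free_fluid_marker(self, calibrated_spec):
        assert v.scale_resistance(calibrated_spec, v.SCENARIOS["none"]) == v.FREE_FLUID


class TestMomentumSink:
    def test_zero_velocity_gives_zero_force(self, calibrated_spec):
        s = momentum_sink(np.zeros(2), np.array([1.0, 0.0]), calibrated_spec)
        assert np.allclose(s, 0.0)

    def test_normal_flow_magnitude(self, calibrated_spec):
        """0.1 m/s normal flow: 29.3 Pa over 50 um = 5.86e5 N/m^3."""
        n = np.array([1.0, 0.0])
        s = momentum_sink(0.1 * n, n, calibrated_spec)
        assert np.linalg.norm(s) == pytest.approx(5.860e5, rel=1e-3)
        # force opposes the velocity
        assert s @ n < 0

    def test_tangential_flow_uses_in_plane_permeability(self, calibrated_spec):
        n = np.array([1.0, 0.0])
        t = np.array([0.0, 1.0])
        s = momentum_sink(0.1 * t, n, calibrated_spec)
        mu = CALIBRATION_FLUID.viscosity
        visc = mu * 0.1 / calibrated_spec.alpha_t
        inert = calibrated_spec.c2 * 0.5 * CALIBRATION_FLUID.density * 0.01
        assert visc == pytest.approx(1.03e6, rel=1e-3)
        assert inert == pytest.approx(1.471e5, rel=1e-3)
        assert np.linalg.norm(s) == pytest.approx(visc + inert, rel=1e-9)
        assert s @ t < 0 and abs(s @ n) < 1e-9

    def test_non_unit_direction_rejected(self, calibrated_spec):
        with pytest.raises(ValueError, match="unit vector"):
            momentum_sink(np.ones(2), np.array([1.0, 1.0]), calibrated_spec)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        vx=st.floats(-1, 1), vz=st.floats(-1, 1),
        theta=st.floats(0, 2 * np.pi),
    )
    def test_sink_is_odd_in_velocity(self, calibrated_spec, vx, vz, theta):
        n = np.array([np.cos(theta), np.sin(theta)])
        vel = np.array([vx, vz])
        s1 = momentum_sink(vel, n, calibrated_spec)
        s2 = momentum_sink(-vel, n, calibrated_spec)
        assert np.allclose(s1, -s2, atol=1e-9)

    def test_line_integral_reproduces_pressure_jump(self, calibrated_spec):
        """S * dm for uniform normal flow equals the Eq-style pressure jump."""
        n = np.array([0.0, 1.0])
        for vel in (0.05, 0.183, 0.6):
            s = momentum_sink(vel * n, n, calibrated_spec)
            assert (s @ n) * calibrated_spec.dm == pytest.approx(
                v.predict_pressure_jump(vel, calibrated_spec), rel=1e-12)


class TestThicknessRescaling:
    @pytest.mark.parametrize("k", [2.0, 10.0, 60.0])
    def test_thickened_layer_preserves_total_drop(self, calibrated_spec, k):
        thick = calibrated_spec.thickened(k * calibrated_spec.dm)
        for vel in (0.05, 0.183):
            assert v.predict_pressure_jump(vel, thick) == pytest.approx(
                v.predict_pressure_jump(vel, calibrated_spec), rel=1e-12)


class TestSampleIO:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "samples.csv"
        write_samples_csv(v.DEFAULT_CALIBRATION_SAMPLES, path)
        back = read_samples_csv(path)
        assert [(s.velocity, s.delta_p) for s in back] == [
            (s.velocity, s.delta_p) for s in v.DEFAULT_CALIBRATION_SAMPLES]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="required columns"):
            read_samples_csv(path)
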