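import numpy as np
import pytest

import vortislot as v
from vortislot import geometry as geom


@pytest.fixture(scope="session")
def calibrated_spec() -> v.PorousLayerSpec:
    """Layer spec from the printed two-point pressure-drop calibration."""
    return v.calibrate_porous_parameters(v.DEFAULT_CALIBRATION_SAMPLES)


@pytest.fixture(scope="session")
def water() -> v.FluidProperties:
    return v.WATER_20C


@pytest.fixture(scope="session")
def poiseuille_solution():
    """Converged Poiseuille channel solve at 64 cells across the gap."""
    grid, zones, bvs = v.build_benchmark_case("poiseuille_channel", (64, 48))
    cfg = v.SolverConfig(max_iterations=600, tolerance=1e-7)
    field, report = v.solve_steady_flow(
        grid, zones, None, v.FREE_FLUID, v.WATER_20C, cfg, bvs=bvs)
    return grid, zones, bvs, field, report


@pytest.fixture(scope="session")
def porous_plug_solution(calibrated_spec):
    grid, zones, bvs = v.build_benchmark_case("porous_plug", (8, 64))
    dirs = v.map_permeability_directions(grid, zones)
    cfg = v.SolverConfig(max_iterations=600, tolerance=1e-8)
    field, report = v.solve_steady_flow(
        grid, zones, dirs, calibrated_spec, v.WATER_20C, cfg, bvs=bvs)
    return grid, zones, bvs, field, report


def _cross_step_solution(scenario: str, calibrated_spec):
    """Axisymmetric cross-step solve (the circular-cone analog of the
    filter); grid and directions rebuilt per scenario fixture."""
    params = v.CrossStepParams(mode="axisymmetric")
    grid, zones = geom.build_cross_step_geometry(params)
    dirs = v.map_permeability_directions(grid, zones)
    eff = v.scale_resistance(calibrated_spec, v.SCENARIOS[scenario])
    cfg = v.SolverConfig(max_iterations=1200, divergence_factor=1e6)
    field, report = v.solve_steady_flow(
        grid, zones, dirs, eff, v.WATER_20C, cfg,
        bvs={"inlet_speed": params.inlet_speed})
    return params, grid, zones, dirs, field, report


@pytest.fixture(scope="session")
def cross_step_original(calibrated_spec):
    """Axisymmetric solve with the calibrated porous resistance."""
    return _cross_step_solution("original", calibrated_spec)


@pytest.fixture(scope="session")
def cross_step_half(calibrated_spec):
    return _cross_step_solution("half", calibrated_spec)


@pytest.fixture(scope="session")
def cross_step_none(calibrated_spec):
    """Axisymmetric solve with the porous layer treated as ordinary water."""
    return _cross_step_solution("none", calibrated_spec)
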