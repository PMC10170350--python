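"""Flow solver: benchmark oracles, conservation, porous coupling."""

import numpy as np
import pytest

import vortislot as v
from vortislot.geometry import Zone, build_benchmark_case
from vortislot.solver import (
    SolverConfig,
    SolverConfigError,
    _Discretization,
    check_mass_conservation,
    solve_steady_flow,
)


class TestConfig:
    def test_bad_relaxation_rejected(self):
        with pytest.raises(SolverConfigError, match="relaxation"):
            SolverConfig(relax_velocity=0.0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(SolverConfigError, match="scheme"):
            SolverConfig(scheme="quick")


class TestPoiseuille:
    def test_profile_matches_parabola_within_one_percent(self, poiseuille_solution):
        grid, zones, bvs, field, report = poiseuille_solution
        assert report.converged
        xc = grid.centers(0)
        H, um = bvs["reference"]["H"], bvs["reference"]["u_mean"]
        exact = 6 * um * (xc / H) * (1 - xc / H)
        j = grid.shape[1] - 2
        err = np.max(np.abs(field.w[:, j] - exact)) / (1.5 * um)
        assert err < 0.01

    def test_mass_imbalance_below_tolerance(self, poiseuille_solution):
        grid, zones, bvs, field, report = poiseuille_solution
        imb, table = check_mass_conservation(field, grid, zones, v.WATER_20C)
        rho_q_in = v.WATER_20C.density * abs(
            table.set_index("patch").flux_m3_per_s["inlet"])
        assert imb < 1e-6 * rho_q_in

    def test_streamfunction_conserved_along_streamline(self, poiseuille_solution):
        """In 2-D the stream function psi = int u dz... is constant on a
        streamline; for Poiseuille psi(x) has a closed form."""
        grid, zones, bvs, field, report = poiseuille_solution
        H, um = bvs["reference"]["H"], bvs["reference"]["u_mean"]

        def psi(x):  # integral of the parabolic profile from 0 to x
            return 6 * um * (x**2 / 2 / H - x**3 / 3 / H**2)

        from vortislot.postprocess import trace_streamline

        seed = (0.3 * H, 0.2 * bvs["reference"]["L"])
        line = trace_streamline(field, seed)
        x_end = line.points[-1][0]
        assert abs(psi(x_end) - psi(seed[0])) / psi(H / 2) < 1e-2


class TestPorousPlug:
    def test_pressure_drop_matches_closed_form(self, porous_plug_solution,
                                               calibrated_spec):
        grid, zones, bvs, field, report = porous_plug_solution
        assert report.converged
        dp = float(np.mean(field.p[:, 0]) - np.mean(field.p[:, -1]))
        expect = -v.predict_pressure_jump(bvs["inlet_speed"], calibrated_spec)
        assert dp == pytest.approx(expect, rel=0.02)

    def test_velocity_uniform_through_plug(self, porous_plug_solution):
        grid, zones, bvs, field, report = porous_plug_solution
        assert np.ptp(field.w) < 1e-10 * bvs["inlet_speed"]

    def test_darcy_only_drop_linear_in_velocity(self, calibrated_spec):
        """With C2 = 0 the plug pressure drop is linear: slope mu*dm/alpha."""
        from dataclasses import replace

        spec0 = replace(calibrated_spec, c2=0.0)
        grid, zones, bvs = build_benchmark_case("porous_plug", (4, 32))
        dirs = v.map_permeability_directions(grid, zones)
        cfg = SolverConfig(max_iterations=300, tolerance=1e-8)
        drops = []
        speeds = (0.1, 0.2)
        for speed in speeds:
            bvs2 = dict(bvs, inlet_speed=speed)
            field, _ = solve_steady_flow(grid, zones, dirs, spec0,
                                         v.WATER_20C, cfg, bvs=bvs2)
            drops.append(float(np.mean(field.p[:, 0]) - np.mean(field.p[:, -1])))
        slope = (drops[1] - drops[0]) / (speeds[1] - speeds[0])
        from vortislot.porous import CALIBRATION_FLUID

        expect = CALIBRATION_FLUID.viscosity * spec0.dm / spec0.alpha_n
        assert slope == pytest.approx(expect, rel=0.01)
        assert drops[0] / speeds[0] == pytest.approx(slope, rel=0.01)


@pytest.fixture(scope="module")
def step_solves():
    out = {}
    for factor in (1.0, 2.0, 3.0):
        grid, zones, bvs = build_benchmark_case("backward_step", (24, 72))
        bvs = dict(bvs)
        bvs["inlet_profile"] = bvs["inlet_profile"] * factor
        cfg = SolverConfig(max_iterations=800)
        field, rep = solve_steady_flow(grid, zones, None, v.FREE_FLUID,
                                       v.WATER_20C, cfg, bvs=bvs)
        out[factor] = (grid, zones, bvs, field)
    return out


class TestBackwardStep:
    @staticmethod
    def _reattachment(grid, zones, bvs, field) -> float:
        wc = field.cell_velocity()[1]
        zc = grid.centers(1)
        L_in = bvs["reference"]["L_in"]
        near_wall = wc[1, :]
        behind = zc > L_in
        neg = behind & (near_wall < 0)
        if not neg.any():
            return 0.0
        return float(zc[neg].max() - L_in)

    def test_recirculation_exists_downstream(self, step_solves):
        grid, zones, bvs, field = step_solves[1.0]
        assert self._reattachment(grid, zones, bvs, field) > 0.0

    def test_reattachment_grows_with_reynolds(self, step_solves):
        lengths = [self._reattachment(*step_solves[f]) for f in (1.0, 2.0, 3.0)]
        assert lengths[0] < lengths[1] < lengths[2]


class TestLidCavity:
    def test_single_primary_vortex_and_no_net_flux(self):
        grid, zones, bvs = build_benchmark_case("lid_cavity", (24, 24))
        cfg = SolverConfig(max_iterations=800)
        field, rep = solve_steady_flow(grid, zones, None, v.FREE_FLUID,
                                       v.WATER_20C, cfg, bvs=bvs)
        # closed box: all boundary fluxes identically zero
        assert np.allclose(field.w[:, 0], 0) and np.allclose(field.w[:, -1], 0)
        # lid drags fluid: w > 0 near the moving x_max wall, return flow below
        wc = field.cell_velocity()[1]
        mid = grid.shape[1] // 2
        assert wc[-1, mid] > 0 and wc[2, mid] < 0
        from vortislot.postprocess import locate_vortex_cores

        cores = locate_vortex_cores(field, zones, grid)
        assert len(cores) >= 1


class TestMassConservationAudit:
    def test_uniform_field_has_zero_imbalance(self):
        grid, zones, bvs = build_benchmark_case("poiseuille_channel", (8, 8))
        field = v.FlowField(
            grid=grid, zones=zones,
            u=np.zeros((9, 8)), w=np.ones((8, 9)), p=np.zeros((8, 8)),
            bvs=bvs,
        )
        imb, _ = check_mass_conservation(field, grid, zones, v.WATER_20C)
        assert imb == 0.0

    def test_constructed_divergent_field_reports_analytic_divergence(self):
        """u = x has div = 1; per-cell imbalance = rho * cell volume."""
        grid, zones, bvs = build_benchmark_case("poiseuille_channel", (8, 8))
        xf = grid.faces(0)
        u = np.tile(xf[:, None], (1, 8))
        field = v.FlowField(grid=grid, zones=zones, u=u,
                            w=np.zeros((8, 9)), p=np.zeros((8, 8)), bvs=bvs)
        d = _Discretization(grid, zones, bvs)
        from vortislot.solver import _cell_imbalance

        imb = _cell_imbalance(d, field.u, field.w, v.WATER_20C.density)
        assert np.allclose(imb, v.WATER_20C.density * grid.cell_volumes())

    def test_global_balance_on_converged_plug(self, porous_plug_solution):
        grid, zones, bvs, field, report = porous_plug_solution
        _, table = check_mass_conservation(field, grid, zones, v.WATER_20C)
        t = table.set_index("patch").flux_m3_per_s
        assert t["outlet"] == pytest.approx(t["inlet"], rel=5e-3)
        # the full-section plug passes the entire flux
        assert t["slot_1"] == pytest.approx(t["inlet"], rel=5e-3)


class TestErrors:
    def test_missing_directions_with_porous_cells(self, calibrated_spec):
        grid, zones, bvs = build_benchmark_case("porous_plug", (4, 16))
        with pytest.raises(SolverConfigError, match="direction"):
            solve_steady_flow(grid, zones, None, calibrated_spec,
                              v.WATER_20C, SolverConfig(max_iterations=5), bvs=bvs)

    def test_three_dimensional_grid_rejected(self):
        grid = v.StructuredGrid(
            (np.full(2, 1.0), np.full(2, 1.0), np.full(2, 1.0)), mode="coarse3d")
        zones = v.ZoneMap(zone=np.full((2, 2, 2), int(Zone.INTERIOR)), boundary={})
        with pytest.raises(SolverConfigError, match="2-D"):
            solve_steady_flow(grid, zones, None, v.FREE_FLUID, v.WATER_20C,
                              SolverConfig(max_iterations=2))


@pytest.fixture(scope="module")
def coarse_planar(calibrated_spec):
    params = v.CrossStepParams(cells_per_step=3)
    grid, zones = v.build_cross_step_geometry(params)
    dirs = v.map_permeability_directions(grid, zones)
    cfg = SolverConfig(max_iterations=600, divergence_factor=1e6)
    field, report = solve_steady_flow(
        grid, zones, dirs, calibrated_spec, v.WATER_20C, cfg,
        bvs={"inlet_speed": params.inlet_speed})
    return params, grid, zones, field, report


class TestPlanarCrossStep:
    """Coarse planar (midfrontal-section) solve: conservation and outflow."""

    def test_every_slot_discharges_filtrate(self, coarse_planar):
        params, grid, zones, field, report = coarse_planar
        from vortislot.solver import slot_outflow

        for s in range(1, params.n_slots + 1):
            assert slot_outflow(field, grid, zones, s) > 0

    def test_global_mass_balance(self, coarse_planar):
        params, grid, zones, field, report = coarse_planar
        _, table = check_mass_conservation(field, grid, zones, v.WATER_20C)
        t = table.set_index("patch").flux_m3_per_s
        assert t["outlet"] == pytest.approx(t["inlet"], rel=5e-3)
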