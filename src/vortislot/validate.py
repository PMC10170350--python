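"""Built-in validation suite.

``fast`` checks the analytic/calibration quantities (seconds); ``full`` adds
benchmark solves and the scaled-down cross-step scenario ordering checks
(minutes).  Failures are report entries, never exceptions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import directions as dirmod
from . import geometry as geom
from . import porous
from . import postprocess
from . import solver as solv


@dataclass
class ValidationTarget:
    id: str
    description: str
    computed: float
    expected: float
    cmp: str          # 'rel' (relative tolerance) or 'le' (computed <= expected)
    tolerance: float
    runtime_s: float

    @property
    def passed(self) -> bool:
        if not np.isfinite(self.computed):
            return False
        if self.cmp == "le":
            return self.computed <= self.expected
        return abs(self.computed - self.expected) <= self.tolerance * abs(self.expected)


@dataclass
class ValidationReport:
    targets: list[ValidationTarget]

    @property
    def all_passed(self) -> bool:
        return all(t.passed for t in self.targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"id": t.id, "description": t.description, "computed": t.computed,
             "expected": t.expected, "cmp": t.cmp, "tolerance": t.tolerance,
             "passed": t.passed, "runtime_s": round(t.runtime_s, 3)}
            for t in self.targets
        ])


def _timed(fn):
    t0 = time.perf_counter()
    val = fn()
    return val, time.perf_counter() - t0


def run_validation_suite(level: str = "fast") -> ValidationReport:
    if level not in ("fast", "full"):
        raise ValueError("level must be 'fast' or 'full'")
    targets: list[ValidationTarget] = []

    def add(id_, desc, fn, expected, cmp="rel", tol=1e-3):
        try:
            val, dt = _timed(fn)
        except Exception:
            val, dt = float("nan"), 0.0
        targets.append(ValidationTarget(id_, desc, float(val), expected, cmp, tol, dt))

    spec = porous.calibrate_porous_parameters(porous.DEFAULT_CALIBRATION_SAMPLES)
    add("t1", "calibrated face permeability alpha_n (m^2)",
        lambda: spec.alpha_n, 2.3468e-10, tol=1e-4)
    add("t2", "calibrated pressure-jump coefficient C2 (1/m)",
        lambda: spec.c2, 29473.0, tol=1e-4)
    add("t3", "predicted pressure jump at 0.183 m/s (Pa)",
        lambda: porous.predict_pressure_jump(0.183, spec), -64.8, tol=5e-3)
    add("t4", "mouth-aperture Reynolds number",
        lambda: postprocess.reynolds_number(0.111, 0.040, porous.WATER_20C),
        4420.0, tol=5e-3)
    half = porous.scale_resistance(spec, porous.HALF)
    add("t5", "half-scenario main viscous resistance (1/m^2)",
        lambda: half.viscous_resistance_n, 2.13e9, tol=5e-3)
    add("t6", "half-scenario inertial resistance (1/m)",
        lambda: half.c2, 14737.0, tol=1e-4)

    if level == "full":
        _add_full_targets(targets, add, spec)
    return ValidationReport(targets=targets)


def _add_full_targets(targets, add, spec):
    water = porous.WATER_20C

    def poiseuille_err():
        grid, zones, bvs = geom.build_benchmark_case("poiseuille_channel", (32, 48))
        cfg = solv.SolverConfig(max_iterations=400, tolerance=1e-6)
        field, _ = solv.solve_steady_flow(grid, zones, None, porous.FREE_FLUID,
                                          water, cfg, bvs=bvs)
        xc = grid.centers(0)
        H, um = bvs["reference"]["H"], bvs["reference"]["u_mean"]
        exact = 6 * um * (xc / H) * (1 - xc / H)
        j = grid.shape[1] - 2
        return float(np.max(np.abs(field.w[:, j] - exact)) / (1.5 * um))

    add("poiseuille", "max deviation from the parabolic profile (fraction)",
        poiseuille_err, 0.01, cmp="le")

    def plug_err():
        grid, zones, bvs = geom.build_benchmark_case("porous_plug", (8, 64))
        dirs = dirmod.map_permeability_directions(grid, zones)
        cfg = solv.SolverConfig(max_iterations=400, tolerance=1e-7)
        field, _ = solv.solve_steady_flow(grid, zones, dirs, spec, water, cfg, bvs=bvs)
        dp = float(np.mean(field.p[:, 0]) - np.mean(field.p[:, -1]))
        expect = -porous.predict_pressure_jump(bvs["inlet_speed"], spec)
        return abs(dp - expect) / expect

    add("porous_plug", "plug pressure drop vs closed form (fraction)",
        plug_err, 0.02, cmp="le")

    def slab_angle():
        grid = geom.StructuredGrid((np.full(8, 1e-3), np.full(8, 1e-3)))
        zone = np.full((8, 8), int(geom.Zone.INTERIOR))
        zone[:, 3:5] = geom.Zone.POROUS
        zone[:, 5:] = geom.Zone.EXTERIOR
        zones = geom.ZoneMap(zone=zone, boundary={})
        d = dirmod.map_permeability_directions(grid, zones)
        vec = d.vectors[:, zone == geom.Zone.POROUS]
        ang = np.degrees(np.arccos(np.clip(vec[1], -1, 1)))
        return float(np.max(ang))

    add("slab_normals", "max direction error on a planar slab (degrees)",
        slab_angle, 1e-6, cmp="le")

    def scenario_ordering():
        params = geom.CrossStepParams(cells_per_step=3, mode="axisymmetric")
        cfg = solv.SolverConfig(max_iterations=1000, divergence_factor=1e6)
        _, table = solv.run_resistance_scenarios(params, spec, water, cfg)
        v = table["mouth_velocity_m_per_s"]
        p = table["mouth_pressure_Pa"]
        ok = (v["original"] < v["half"] < v["none"]) and (
            p["original"] > p["half"] > p["none"])
        return 0.0 if ok else 1.0

    add("scenario_ordering",
        "mouth velocity rises / pressure falls as resistance is removed (0 = pass)",
        scenario_ordering, 0.5, cmp="le")
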