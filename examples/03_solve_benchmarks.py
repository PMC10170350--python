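"""Validate the flow solver against closed-form benchmark cases.

Poiseuille channel: the steady profile between no-slip plates is the
parabola w(x) = 6 w_mean (x/H)(1 - x/H).  Porous plug: a uniform stream
forced through a resistive layer loses exactly the calibrated pressure
jump.  Both give the solver a known answer to hit.
"""

import numpy as np

import vortislot as v

# --- Poiseuille channel -----------------------------------------------
grid, zones, bvs = v.build_benchmark_case("poiseuille_channel", (64, 48))
cfg = v.SolverConfig(max_iterations=600, tolerance=1e-7)
field, report = v.solve_steady_flow(grid, zones, None, v.FREE_FLUID,
                                    v.WATER_20C, cfg, bvs=bvs)
xc = grid.centers(0)
H, um = bvs["reference"]["H"], bvs["reference"]["u_mean"]
exact = 6 * um * (xc / H) * (1 - xc / H)
err = np.max(np.abs(field.w[:, -2] - exact)) / (1.5 * um)
print(f"Poiseuille: converged in {report.iterations} iterations, "
      f"max profile error {100 * err:.3f}% of the peak velocity")

# --- porous plug ------------------------------------------------------
spec = v.calibrate_porous_parameters(v.DEFAULT_CALIBRATION_SAMPLES)
grid, zones, bvs = v.build_benchmark_case("porous_plug", (8, 64))
dirs = v.map_permeability_directions(grid, zones)
field, report = v.solve_steady_flow(grid, zones, dirs, spec, v.WATER_20C,
                                    v.SolverConfig(max_iterations=400, tolerance=1e-8),
                                    bvs=bvs)
dp = float(np.mean(field.p[:, 0]) - np.mean(field.p[:, -1]))
expect = -v.predict_pressure_jump(bvs["inlet_speed"], spec)
print(f"porous plug: pressure drop {dp:.2f} Pa vs closed form {expect:.2f} Pa "
      f"({100 * abs(dp - expect) / expect:.2g}% off)")
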