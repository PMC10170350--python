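"""Dividing streamlines and particle-exclusion radii of the cross-step filter.

Not all water entering the mouth reaches every slot: a dividing streamline
separates the flow captured by each slot from the flow continuing medially.
Its closest approach to the interior filter surface bounds the radius of a
spherical particle that can still be carried into the slot; larger
particles are geometrically excluded (Stokes number 0, no rebound).

Takes a couple of minutes: one steady solve plus streamline bisection.
"""

import vortislot as v
from vortislot import postprocess as post

spec = v.calibrate_porous_parameters(v.DEFAULT_CALIBRATION_SAMPLES)
params = v.CrossStepParams(mode="axisymmetric")
grid, zones = v.build_cross_step_geometry(params)
dirs = v.map_permeability_directions(grid, zones)
field, report = v.solve_steady_flow(
    grid, zones, dirs, spec, v.WATER_20C,
    v.SolverConfig(max_iterations=1200),
    bvs={"inlet_speed": params.inlet_speed})

for slot in range(1, params.n_slots + 1):
    res = post.find_dividing_streamline(field, slot)
    if not res.found:
        print(f"slot {slot}: no dividing streamline "
              "(all remaining flow is captured by this and later slots)")
        continue
    gap = params.slot_width
    print(f"slot {slot}: dividing seed offset {1e3 * res.seed_offset:.2f} mm, "
          f"exclusion radius {1e3 * res.exclusion_radius:.2f} mm "
          f"({'no ' if res.exclusion_radius < gap / 2 else ''}blockage risk: "
          f"compare to half slot gap {1e3 * gap / 2:.1f} mm)")

# a particle larger than the slot-1 exclusion radius must pass the slot
res1 = post.find_dividing_streamline(field, 1)
if res1.found:
    start = (res1.seed_offset, res1.streamline.points[0][1])
    path = post.trace_particle_path(field, 1.2 * res1.exclusion_radius, start)
    print(f"particle of radius 1.2 x exclusion radius seeded on the dividing "
          f"streamline: fate = {path.fate}")
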