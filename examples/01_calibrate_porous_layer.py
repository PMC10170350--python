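"""Calibrate the porous-layer resistance from pressure-drop samples.

A thin filter mesh (here: the gill-raker mesh of a suspension-feeding fish,
pore size ~140 um, layer thickness 50 um) is characterised by two numbers:
the face permeability alpha (Darcy, viscous) and the pressure-jump
coefficient C2 (inertial).  Two pressure-drop measurements at different
approach velocities determine both.
"""

import vortislot as v

spec = v.calibrate_porous_parameters(
    v.DEFAULT_CALIBRATION_SAMPLES,   # (0.1 m/s, 29.3 Pa), (0.5 m/s, 293.6 Pa)
    v.CALIBRATION_FLUID,             # water at 20 C
    dm=50e-6,                        # layer thickness (m)
)

print(f"face permeability alpha_n = {spec.alpha_n:.5g} m^2")
print(f"pressure-jump coefficient C2 = {spec.c2:.1f} 1/m")
print(f"main viscous resistance 1/alpha_n = {spec.viscous_resistance_n:.4g} 1/m^2")

# out-of-sample check: the model evaluated at the flow-tank speed
jump = v.predict_pressure_jump(0.183, spec)
print(f"predicted pressure jump at 0.183 m/s = {jump:.1f} Pa")
print("(negative: pressure falls across the layer in the flow direction)")
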