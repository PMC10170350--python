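# vortislot

Desk-scale modelling of **vortical cross-step filtration** — the flow
mechanism of the oral filter in ram suspension-feeding fish. The filter is
a tapered cone whose wall alternates solid ribs (branchial arches, acting
as backward-facing steps) with slots floored by a fine porous mesh (the
gill rakers). Water entering the open mouth spins up a vortex inside each
slot; filtrate leaves through the mesh while particles are concentrated
and carried along the slots. `vortislot` is for biomechanics and
biomimetic-filtration researchers who want to explore this mechanism
computationally without an industrial CFD stack.

The package provides, as a library plus a thin `vortislot` CLI:

- **Porous-layer calibration** (`vortislot.porous`). The mesh is a
  continuum momentum sink: the pressure jump across a layer of thickness
  Δm at normal approach velocity v is

  Δp = −(μ/α·v + C2·½ρv²)·Δm

  with face permeability α (Darcy, viscous) and pressure-jump coefficient
  C2 (inertial). Two pressure-drop samples at distinct velocities
  determine both exactly; more are fit by least squares. Anisotropy: main
  permeability α_n along the per-cell layer normal, tangential
  α_t = 10⁻¹⁰ m² in plane, C2 isotropic.
- **Permeability-direction mapping** (`vortislot.directions`). For an
  irregular layer (part of a tapered cone) the per-cell main-permeability
  direction is the normalised gradient of a scalar solved by a Laplace
  problem between the two bounding water zones (interior 0, exterior 1).
- **A steady incompressible finite-volume solver**
  (`vortislot.solver`): SIMPLE pressure–velocity coupling on staggered
  structured grids, planar-2D and axisymmetric modes, laminar, with the
  anisotropic Darcy + inertial sink applied in the mapped directions, and
  a scenario runner that compares the calibrated resistance against
  halved and removed resistance.
- **Flow diagnostics** (`vortislot.postprocess`): streamlines, vortex-core
  detection and slot-confinement classification, per-slot outflow/shear
  profiles, centreline profiles, dividing streamlines with
  particle-exclusion radii, and zero-Stokes-number particle paths with
  wall sliding.

## Worked example

Calibrate the mesh resistance from two pressure-drop observations across a
50 µm layer and predict the jump at the flow-tank speed
(`examples/01_calibrate_porous_layer.py`):

```
$ python examples/01_calibrate_porous_layer.py
face permeability alpha_n = 2.3468e-10 m^2
pressure-jump coefficient C2 = 29473.1 1/m
main viscous resistance 1/alpha_n = 4.261e+09 1/m^2
predicted pressure jump at 0.183 m/s = -64.8 Pa
(negative: pressure falls across the layer in the flow direction)
```

The two samples (29.3 Pa at 0.1 m/s, 293.6 Pa at 0.5 m/s) pin the viscous
and inertial coefficients; −64.8 Pa at 0.183 m/s is an out-of-sample
prediction of the same model. The solver benchmarks
(`examples/03_solve_benchmarks.py`) then show the finite-volume scheme
hitting its closed forms:

```
Poiseuille: converged in 376 iterations, max profile error 0.023% of the peak velocity
porous plug: pressure drop 64.79 Pa vs closed form 64.79 Pa (3.8e-10% off)
```

`examples/04_cross_step_scenarios.py` (a few minutes) solves the filter
for the original / half / none resistance scenarios and prints the
comparison table: mouth-centre velocity rises and pressure falls as
resistance is removed, vortex cores sit inside the slots with the
calibrated mesh and outside the filter without it, and most outflow leaves
through the posterior third of each slot.
`examples/05_particle_exclusion.py` estimates, per slot, the largest
spherical particle the flow can carry into the slot entrance.

A CLI wraps the same pipeline:

```sh
vortislot calibrate --samples samples.csv --dm 50e-6
vortislot solve --config run.yaml --scenario original
vortislot scenario-report --config run.yaml
vortislot validate --level fast
```

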