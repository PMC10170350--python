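# Methods

`vortislot` models vortical cross-step filtration: the flow through an
idealised fish oral filter built from backward-facing steps (branchial
arches) whose inter-step slots have porous floors (the gill-raker mesh).
Water enters the open mouth of a tapered cone, vortices are trapped in the
slots, and filtrate leaves through the porous slot floors while the closed
posterior wall represents the oesophagus. This note records the model, its
assumptions, the numerical choices, and what the desk-scale analog can and
cannot be expected to reproduce.

## Porous-layer model

A thin filter mesh is treated as a continuum momentum sink rather than a
resolved pore geometry. The pressure jump across a layer of thickness
Δm for normal approach velocity v is

    Δp = −(μ/α · v + C2 · ½ρ v²) · Δm

with face permeability α (m², Darcy/viscous term) and pressure-jump
coefficient C2 (1/m, inertial term). Two pressure-drop observations at
distinct velocities determine (α, C2) by a 2×2 linear solve in x = μ/α and
y = C2ρ/2; more samples are fit by ordinary least squares on the same
linearisation. Defaults reproduce the micro-scale calibration of a 50 µm
mesh layer: samples (0.1 m/s, 29.3 Pa) and (0.5 m/s, 293.6 Pa) with
μ = 1.03×10⁻³ Pa s, ρ = 998.2 kg/m³ give α = 2.3468×10⁻¹⁰ m² and
C2 = 29 473 m⁻¹, and predict −64.8 Pa at 0.183 m/s.

The layer is anisotropic in its viscous term: the main (through-layer)
permeability α_n applies along a per-cell unit direction **n**, a lower
tangential permeability α_t = 10⁻¹⁰ m² in the layer plane. The inertial
term is isotropic. The full sink is

    S = −[ μ( (1/α_n) n nᵀ + (1/α_t)(I − n nᵀ) ) v + C2 ½ρ |v| v ].

Two water-viscosity conventions appear in the sources this model follows
(1.03 mPa s in the calibration, 1.003 mPa s for the bulk flow). The package
keeps them separate: `CALIBRATION_FLUID` is used for calibration and for
building the solver's sink tensors — so the integrated sink always equals
the calibrated pressure jump exactly — while `WATER_20C` (1.003 mPa s) is
the bulk-flow default and is the value that makes the mouth Reynolds number
ρvD/μ = 4420 at v = 0.111 m/s, D = 40 mm.

Resistance scenarios scale 1/α_n, 1/α_t and C2 by a multiplier: `original`
(1), `half` (0.5 → 2.13×10⁹ m⁻², 5×10⁹ m⁻², 14 737 m⁻¹) and `none` (0),
the latter returning a free-fluid marker so the solver treats the layer as
ordinary water.

## Geometry

The filter is a cone tapering from the mouth (aperture radius 20 mm,
hydraulic diameter 40 mm) to a closed back 60 mm posterior. Its wall is
n_slots = 5 repeat units of one solid rib (width 3 mm, protruding
3 mm = one step height into the lumen) followed by one porous-floored slot
(width 9 mm); slot/step aspect ratio 3 keeps the grooves in the d-type
regime where a recirculating vortex stays confined. The rib and slot
dimensions are configurable stand-ins chosen to fill the stated 60 mm
filter length — the reference physical model's exact rib cross-section is
not published — and a warning (not an error) is raised if slot/step > 4.

Everything is discretised on axis-aligned structured grids with stair-step
solid masking; spacings are uniform (step_height / cells_per_step, default
0.75 mm) over the filter envelope and geometrically graded toward the far
field. Two solver-facing modes exist: `planar2d`, the midfrontal section
with a symmetry centreline, and `axisymmetric`, the cone approximated as
circular with full 2π metric factors. The domain extends 10 filter lengths
axially and 5 mouth radii laterally (blockage < 5%), with a uniform
velocity inlet (0.183 m/s), zero-gauge pressure outlet, free-slip far
boundary and no-slip filter surfaces.

Zone labels partition the cells into interior water (inside the cone),
exterior water, porous layer (one cell thick, one strip per slot) and
solid. Interior and exterior water meet only at the mouth aperture; the
zone map records those aperture faces explicitly, and the separation
property (every other interior→exterior path crosses porous or solid) is
asserted on every generated geometry.

## Permeability-direction mapping

Because the porous floors are parts of a tapered cone, no closed formula
gives their per-cell normal. The mapping solves a discrete Laplace problem
on the porous cells with Dirichlet data from the bounding zones (interior
water 0, exterior water 1, solid faces no-flux) and takes the per-cell
weighted-least-squares gradient of the solved scalar, normalised to unit
length. The gradient points from interior to exterior by construction. The
linear system is solved directly to residual < 10⁻¹⁰ rather than for a
fixed iteration count, making the result mesh-independent for thin layers;
the 0/1 boundary values are arbitrary (any ordered pair yields the same
directions). On analytic fixtures the vectors are exact for a planar slab
and within 2° of the radial normal for a cylindrical annulus at ≥ 48 cells
across the quadrant, with error decreasing under refinement.

## Flow solver

Steady incompressible Navier–Stokes with the porous sink, discretised by
finite volumes on a staggered (MAC) arrangement — x/r-velocity on
constant-x faces, z-velocity on constant-z faces, pressure at centres —
and solved by SIMPLE pressure–velocity coupling with sparse direct solves
of the momentum and pressure-correction systems each outer iteration.

Numerical choices, in order of consequence:

- **Laminar equations.** The full-scale reference computation used a
  four-equation SST transition model at Re ≈ 4400–7300. At desk scale the
  large vortical structures this package diagnoses are geometry- and
  resistance-dominated; turbulence modelling is out of scope. Quantitative
  disagreement attributable to this is discussed under Limitations.
- **Convection: first-order upwind by default.** A second-order-upwind
  deferred correction is implemented (`scheme="second_order_upwind"`) and
  fine for the benign benchmarks, but it destabilises the separated
  cross-step flow on these coarse grids even with strong under-relaxation,
  so robustness wins the default.
- **Porous terms.** The Darcy term is implicit in the momentum diagonal;
  the inertial term is Picard-linearised with |v| lagged one outer
  iteration. This is stable up to the 10¹⁰ m⁻² resistances used here. Face
  coefficients average the two adjacent cells' half-volumes, which makes
  the integrated plug-flow pressure drop exact (verified to 10⁻¹² against
  the closed form).
- **Layer thickening.** A 50 µm layer in a 60 mm domain is numerically
  hostile, so the porous strip is built one grid cell thick and its
  coefficients rescaled per cell by Δm/t_cell (preserving (1/α)·Δm and
  C2·Δm, hence the total pressure jump; t_cell is the cell extent projected
  on the permeability direction).
- **Under-relaxation 0.5 (velocity) / 0.2 (pressure).** At the conventional 0.7/0.3
  the cross-step case blows up around iteration 300; 0.5/0.2 converges
  steadily on every case in the suite, so those are the defaults.
- **Outlet.** Zero-gradient outlet velocity rescaled each iteration for
  exact global mass balance; pressure correction pinned at one reference
  cell; the final pressure field is shifted to zero mean over the outlet
  (the gauge reference). Initialisation is deterministic (inlet velocity
  everywhere, zero pressure); the solver contains no randomness.
- **Convergence** is declared when scaled residuals (continuity scaled by
  inlet mass flux, momentum by a boundary-velocity momentum scale) drop
  below 10⁻⁵ *and* the filter drag monitor has been flat to 0.1% over 100
  iterations; the iteration cap (default 2000) is a cap, not the criterion.
  The axisymmetric original-resistance case converges in ≈ 850 iterations;
  the zero-resistance case stalls near 10⁻²–10⁻³ continuity (physically
  unsteady wake at these Reynolds numbers) and is reported unconverged
  while its time-mean-like iterate is still usable for the qualitative
  diagnostics.

Benchmarks wired into the test suite: Poiseuille channel (profile within
1% of the parabola at 64 cells across the gap), porous plug (pressure drop
within 2% of the calibrated jump; to machine precision in practice),
backward-facing step (recirculation present, reattachment length growing
with Re), lid-driven cavity (single primary vortex, closed-box fluxes
zero), and a constructed non-solenoidal field whose audit reproduces the
analytic divergence exactly.

## Diagnostics

- **Streamlines**: RK4 with adaptive step ≤ half the local cell size;
  termination at the outlet, a boundary, a porous layer (recording the
  slot), a step cap, or a stagnant seed.
- **Vortex cores**: interior extrema of the streamfunction (Stokes
  streamfunction in axisymmetric mode) that also carry swirling strength
  λ_ci above a threshold (30% of the regional maximum by default). A
  closed recirculation has a streamfunction extremum at its centre, so
  shear layers — vortical but not recirculating — are excluded by
  construction; plain λ_ci maxima were tried first and fire on the
  mouth-lip shear layer in every scenario. The search region is the slot
  neighbourhood (anterior edge of slot 1 to the closed back, rib-crest
  level to three step heights beyond the floor); "inside a slot" means
  between rib crest and porous floor, the layer itself counting as
  outside. In 2-D sections the helix-axis velocity of a core is not
  observable and is reported as NaN.
- **Slot fluxes**: per-axial-station outflow through the exterior faces of
  each porous strip; anterior/middle/posterior thirds by equal arc length;
  near-floor shear stress and tangential velocity one cell medial of the
  layer.
- **Dividing streamlines**: bisection on the seed's transverse coordinate
  at the mouth plane between a streamline that exits via slot ≤ k and one
  that continues past slot k (bracket tolerance 10⁻⁵ m); a trace ending on
  a rib crest counts as "continues", which biases the bracket toward
  larger exclusion radii. The minimum distance from the dividing
  streamline to the interior filter surface (shapely distance to the
  stair-step surface polyline) is the particle-exclusion radius. Verified
  against the closed-form capture width m/U of a line sink in a uniform
  stream.
- **Particle paths** (Stokes number 0, no rebound): the centre is advected
  with the local fluid velocity; within one radius of a blocking surface
  (solid or porous faces) it is projected back to the standoff distance.
  When several walls leave no feasible position (throat narrower than 2r)
  the particle cannot advance and is reported excluded/stalled.

## What the desk-scale analog reproduces, and what it does not

Reproduced (axisymmetric solves, calibrated resistance unless stated):

- calibration, prediction and scenario arithmetic exactly;
- a vortex core confined inside every one of the five slots; with zero
  resistance every recirculation centre moves 1–3 mm outside the filter
  surface (the published contrast is "about 2 mm outside");
- posterior-third outflow exceeding anterior-third in every slot, and
  exterior-to-interior inflow at the anterior slot regions in the
  zero-resistance scenario;
- mouth-centre velocity strictly increasing and pressure strictly
  decreasing across original → half → none;
- centreline pressure rising toward the closed back;
- anterior-directed (reversed) flow along the porous floor in the
  anterior two-thirds of every slot.

Not reproduced quantitatively:

- The mouth-centre probes come out at ≈ 0.149 m/s and ≈ 8.2 Pa against the
  published 0.111 m/s and 11.2 Pa — the analog passes ~35% more flow. The
  candidate causes, in estimated order: the stand-in rib/slot cross-
  sections (unpublished in the source; they set the slot areas and hence
  the resistance balance), the circular approximation of the elliptical
  cone, and the laminar equations. The scenario orderings are insensitive
  to all three.
- Floor-flow reversal reaches the middle third only in slots 1–3; in the
  two posterior slots the taper concentrates suction and keeps the
  mid-slot floor flow outward/posterior.
- Mouth velocity wobbles ~2.5% (non-monotonically) across cells_per_step
  2/3/4, so strict grid convergence of the probes is not demonstrated at
  desk scale; the qualitative diagnostics are unchanged across those
  grids.
- Published dividing-streamline distances in millimetres derive from the
  full 3-D geometry and are treated as method demonstrations here, not
  validation targets.

## Problem sizes and runtimes

Defaults were chosen so the whole pipeline runs on one CPU core in
minutes: cells_per_step = 4 gives 56×193 cells axisymmetric (≈ 85 s to
convergence) and the same planar; benchmarks run at 64×48 and below. The
synthetic geometry is regenerated programmatically everywhere — no stored
fixtures.
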