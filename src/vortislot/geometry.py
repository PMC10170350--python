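"""Structured grids and zone maps for cross-step filter and benchmark cases.

The cross-step filter is the oral filter of a ram suspension-feeding fish,
idealised as a tapered cone whose wall is a sequence of solid ribs (the
branchial arches, acting as backward-facing steps) alternating with open
slots whose outer surface carries a thin porous layer (the gill-raker mesh).
Water enters through the mouth aperture, the back of the cone is closed, and
filtrate leaves through the porous slot floors.

Geometry is represented on axis-aligned structured grids with stair-step
solid masking.  Two solver-facing modes exist: ``planar2d`` (the midfrontal
section with a symmetry centreline) and ``axisymmetric`` (the cone
approximated as circular).  Axis 0 is the lateral/radial coordinate x (or r),
axis 1 is the axial coordinate z, increasing anterior to posterior.  All
units SI; indices 0-based; coordinates are cell centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Optional

import numpy as np


class Zone(IntEnum):
    SOLID = 0
    INTERIOR = 1
    POROUS = 2
    EXTERIOR = 3


class BoundaryTag:
    VELOCITY_INLET = "velocity_inlet"
    PRESSURE_OUTLET = "pressure_outlet"
    SLIP_WALL = "slip_wall"
    NOSLIP_WALL = "noslip_wall"
    SYMMETRY = "symmetry"

    ALL = (VELOCITY_INLET, PRESSURE_OUTLET, SLIP_WALL, NOSLIP_WALL, SYMMETRY)


class GeometryConfigError(ValueError):
    """Raised when geometry parameters violate a constraint."""


@dataclass(frozen=True)
class StructuredGrid:
    """Axis-aligned structured grid (2 axes here; spacings may be graded).

    spacings : per-axis arrays of cell sizes (m), all > 0
    mode : 'planar2d' | 'axisymmetric' | 'coarse3d'
    """

    spacings: tuple[np.ndarray, ...]
    mode: str = "planar2d"

    def __post_init__(self) -> None:
        if self.mode not in ("planar2d", "axisymmetric", "coarse3d"):
            raise GeometryConfigError(f"unknown grid mode {self.mode!r}")
        for s in self.spacings:
            if np.any(np.asarray(s) <= 0):
                raise GeometryConfigError("all cell spacings must be positive")
            if len(s) < 1:
                raise GeometryConfigError("each axis needs at least one cell")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.spacings)

    @property
    def ndim(self) -> int:
        return len(self.spacings)

    def faces(self, axis: int) -> np.ndarray:
        """Face coordinates along an axis (length n+1, starting at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.spacings[axis])])

    def centers(self, axis: int) -> np.ndarray:
        f = self.faces(axis)
        return 0.5 * (f[:-1] + f[1:])

    # -- metric factors (2-D modes) -------------------------------------
    # planar2d: unit span in the out-of-plane direction.
    # axisymmetric: full-revolution volumes/areas; axis 0 is radius r >= 0.

    def cell_volumes(self) -> np.ndarray:
        dx, dz = self.spacings[0], self.spacings[1]
        vol = np.outer(dx, dz)
        if self.mode == "axisymmetric":
            vol = vol * (2.0 * np.pi * self.centers(0))[:, None]
        return vol

    def face_areas_x(self) -> np.ndarray:
        """Areas of constant-x faces, shape (nx+1, nz)."""
        dz = self.spacings[1]
        a = np.tile(dz, (self.shape[0] + 1, 1))
        if self.mode == "axisymmetric":
            a = a * (2.0 * np.pi * self.faces(0))[:, None]
        return a

    def face_areas_z(self) -> np.ndarray:
        """Areas of constant-z faces, shape (nx, nz+1)."""
        dx = self.spacings[0]
        a = np.tile(dx[:, None], (1, self.shape[1] + 1))
        if self.mode == "axisymmetric":
            a = a * (2.0 * np.pi * self.centers(0))[:, None]
        return a


@dataclass
class ZoneMap:
    """Per-cell zone labels, boundary tags and cross-step metadata.

    zone : int array, values from :class:`Zone`
    boundary : face-name ('x_min','x_max','z_min','z_max') -> BoundaryTag
    slot_id : per-cell slot index for porous cells (1-based, anterior to
        posterior), -1 elsewhere
    openings : boolean face mask pairs where interior and exterior fluid are
        allowed to meet (the mouth aperture); stored as a list of
        ((i, j), (i2, j2)) face-adjacent cell index pairs
    layout : CrossStepLayout for cross-step geometries, else None
    """

    zone: np.ndarray
    boundary: dict[str, str]
    slot_id: np.ndarray = None  # type: ignore[assignment]
    openings: list = field(default_factory=list)
    layout: Optional["CrossStepLayout"] = None

    def __post_init__(self) -> None:
        if self.slot_id is None:
            self.slot_id = np.full(self.zone.shape, -1, dtype=int)
        for name, tag in self.boundary.items():
            if tag not in BoundaryTag.ALL:
                raise GeometryConfigError(f"unknown boundary tag {tag!r} on {name}")

    @property
    def n_slots(self) -> int:
        ids = np.unique(self.slot_id[self.slot_id >= 0])
        return len(ids)


@dataclass(frozen=True)
class CrossStepParams:
    """Parameters of the idealised cross-step filter.

    Lengths in metres.  The filter spans ``filter_length`` from the mouth
    rim to the closed posterior wall; each of ``n_slots`` repeat units is one
    rib (width ``rib_width``, protruding ``step_height`` into the lumen)
    followed by one porous-floored slot (width ``slot_width``).  The rib/slot
    dimensions are configurable stand-ins consistent with a d-type groove
    regime (slot/step aspect ratio about 3), not measured values.
    """

    n_slots: int = 5
    filter_length: float = 0.060
    mouth_diameter: float = 0.040
    step_height: float = 0.003
    slot_width: float = 0.009
    rib_width: float = 0.003
    dm: float = 50e-6
    back_inner_radius: float = 0.006
    domain_length: float = 0.60
    domain_half_width: float = 0.100
    mouth_position: float = 0.12
    inlet_speed: float = 0.183
    cells_per_step: int = 4
    mode: str = "planar2d"

    def __post_init__(self) -> None:
        lengths = {
            "filter_length": self.filter_length,
            "mouth_diameter": self.mouth_diameter,
            "step_height": self.step_height,
            "slot_width": self.slot_width,
            "rib_width": self.rib_width,
            "dm": self.dm,
            "back_inner_radius": self.back_inner_radius,
            "domain_length": self.domain_length,
            "domain_half_width": self.domain_half_width,
            "mouth_position": self.mouth_position,
        }
        for name, val in lengths.items():
            if val <= 0:
                raise GeometryConfigError(f"{name} must be positive (got {val})")
        if self.n_slots < 1:
            raise GeometryConfigError("n_slots must be >= 1")
        pitch = self.n_slots * (self.slot_width + self.rib_width)
        if pitch > self.filter_length * (1 + 1e-12):
            raise GeometryConfigError(
                f"n_slots * (slot_width + rib_width) = {pitch:.6g} m exceeds "
                f"filter_length = {self.filter_length:.6g} m"
            )
        if self.mouth_position + self.filter_length >= self.domain_length:
            raise GeometryConfigError("filter does not fit inside domain_length")
        if self.mouth_diameter / 2 + self.step_height >= self.domain_half_width:
            raise GeometryConfigError("filter does not fit inside domain_half_width")
        if self.slot_width / self.step_height > 4:
            warnings.warn(
                "slot_width/step_height > 4 leaves the d-type groove regime; "
                "the slot vortex may no longer stay confined",
                stacklevel=2,
            )

    @property
    def mouth_radius(self) -> float:
        return self.mouth_diameter / 2


@dataclass
class CrossStepLayout:
    """Derived axial/radial layout of the filter, in physical coordinates."""

    params: CrossStepParams
    z_mouth: float
    z_back: float
    rib_spans: list[tuple[float, float]]
    slot_spans: list[tuple[float, float]]
    porous_thickness: float

    def outer_radius(self, z) -> np.ndarray:
        """Radius of the cone outer surface (porous-layer floor) at z."""
        p = self.params
        r0 = p.mouth_radius + p.step_height
        r1 = p.back_inner_radius + p.step_height
        t = np.clip((np.asarray(z) - self.z_mouth) / (self.z_back - self.z_mouth), 0, 1)
        return r0 + (r1 - r0) * t

    def rib_inner_radius(self, z) -> np.ndarray:
        return self.outer_radius(z) - self.params.step_height


def graded_spacings(length: float, h_fine: float, growth: float = 1.15,
                    h_max_ratio: float = 8.0) -> np.ndarray:
    """Cell sizes growing geometrically from h_fine, rescaled to sum to length."""
    sizes = []
    h, total = h_fine, 0.0
    while total < length:
        sizes.append(h)
        total += h
        h = min(h * growth, h_fine * h_max_ratio)
    s = np.array(sizes)
    return s * (length / s.sum())


def build_cross_step_geometry(params: CrossStepParams) -> tuple[StructuredGrid, ZoneMap]:
    """Build the stair-step grid and zone map of the cross-step filter.

    Returns a grid in the requested 2-D mode and a ZoneMap with exactly
    ``n_slots`` porous strips, solid ribs and posterior wall, interior and
    exterior water zones meeting only at the mouth aperture, and boundary
    tags: uniform velocity inlet upstream, zero-gauge pressure outlet
    downstream, free-slip far lateral boundary, symmetry/axis centreline.
    """
    p = params
    if p.mode not in ("planar2d", "axisymmetric"):
        raise GeometryConfigError(
            f"cross-step geometry supports planar2d/axisymmetric, not {p.mode!r}"
        )
    h = p.step_height / p.cells_per_step

    # --- axial (z) axis: graded upstream, uniform over filter, graded wake
    n_rib = max(1, round(p.rib_width / h))
    n_slot = max(1, round(p.slot_width / h))
    dz_rib = p.rib_width / n_rib
    dz_slot = p.slot_width / n_slot

    up = graded_spacings(p.mouth_position, h)[::-1]
    z_mouth = up.sum()
    fil: list[float] = []
    rib_spans, slot_spans = [], []
    z = z_mouth
    for _ in range(p.n_slots):
        rib_spans.append((z, z + p.rib_width))
        fil += [dz_rib] * n_rib
        z += p.rib_width
        slot_spans.append((z, z + p.slot_width))
        fil += [dz_slot] * n_slot
        z += p.slot_width
    slack = p.filter_length - p.n_slots * (p.rib_width + p.slot_width)
    if slack > 0.5 * h:
        n_sl = max(1, round(slack / h))
        fil += [slack / n_sl] * n_sl
        z += slack
    z_back = z
    fil += [dz_rib] * n_rib  # solid posterior wall, one rib thick
    z += p.rib_width
    down = graded_spacings(p.domain_length - z, h)
    dzs = np.concatenate([up, np.array(fil), down])

    # --- lateral (x/r) axis: uniform over the filter envelope, graded beyond
    r_env = p.mouth_radius + p.step_height + 3 * h
    n_fine_x = int(np.ceil(r_env / h))
    fine_x = np.full(n_fine_x, h)
    out_x = graded_spacings(p.domain_half_width - n_fine_x * h, h)
    dxs = np.concatenate([fine_x, out_x])

    grid = StructuredGrid(spacings=(dxs, dzs), mode=p.mode)
    xc, zc = grid.centers(0), grid.centers(1)
    nx, nz = grid.shape

    layout = CrossStepLayout(
        params=p, z_mouth=z_mouth, z_back=z_back,
        rib_spans=rib_spans, slot_spans=slot_spans, porous_thickness=h,
    )

    zone = np.full((nx, nz), int(Zone.EXTERIOR), dtype=int)
    slot_id = np.full((nx, nz), -1, dtype=int)
    t_por = h
    in_rib = np.zeros(nz, dtype=bool)
    in_slot = np.full(nz, -1, dtype=int)
    for a, b in rib_spans:
        in_rib |= (zc > a) & (zc < b)
    for k, (a, b) in enumerate(slot_spans):
        in_slot[(zc > a) & (zc < b)] = k + 1

    for j in range(nz):
        zj = zc[j]
        if zj <= z_mouth or zj >= z_back + p.rib_width:
            continue  # upstream / behind back wall: exterior water
        r_out = float(layout.outer_radius(zj))
        r_in = r_out - p.step_height
        if zj >= z_back:  # posterior solid wall
            zone[xc < r_out + t_por, j] = Zone.SOLID
        elif in_rib[j]:
            zone[xc < r_in, j] = Zone.INTERIOR
            zone[(xc >= r_in) & (xc < r_out + t_por), j] = Zone.SOLID
        elif in_slot[j] > 0:
            zone[xc < r_out, j] = Zone.INTERIOR
            por = (xc >= r_out) & (xc < r_out + t_por)
            zone[por, j] = Zone.POROUS
            slot_id[por, j] = in_slot[j]
        else:  # slack between last slot and back wall: plain interior lumen
            zone[xc < r_out, j] = Zone.INTERIOR

    # mouth aperture: faces between the upstream exterior column and the
    # first interior column are the allowed interior/exterior meeting place
    openings = []
    j_mouth = int(np.searchsorted(zc, z_mouth))
    for i in range(nx):
        if zone[i, j_mouth] == Zone.INTERIOR and zone[i, j_mouth - 1] == Zone.EXTERIOR:
            openings.append(((i, j_mouth - 1), (i, j_mouth)))

    boundary = {
        "x_min": BoundaryTag.SYMMETRY,
        "x_max": BoundaryTag.SLIP_WALL,
        "z_min": BoundaryTag.VELOCITY_INLET,
        "z_max": BoundaryTag.PRESSURE_OUTLET,
    }
    zones = ZoneMap(zone=zone, boundary=boundary, slot_id=slot_id,
                    openings=openings, layout=layout)
    _validate_zones(zones)
    return grid, zones


def _validate_zones(zones: ZoneMap) -> None:
    n_porous_strips = zones.n_slots
    if zones.layout is not None and n_porous_strips != zones.layout.params.n_slots:
        raise GeometryConfigError(
            f"constructed {n_porous_strips} porous strips, expected "
            f"{zones.layout.params.n_slots}"
        )
    leaks = find_zone_leaks(zones)
    if leaks:
        raise GeometryConfigError(
            f"interior and exterior fluid meet outside the declared aperture "
            f"at {len(leaks)} cell faces, first at {leaks[0]}"
        )


def find_zone_leaks(zones: ZoneMap) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Interior/exterior face adjacencies not covered by declared openings.

    An empty list certifies the zone-separation property: any path from
    interior to exterior water crosses a porous or solid cell or the declared
    aperture.
    """
    z = zones.zone
    allowed = set()
    for a, b in zones.openings:
        allowed.add((tuple(a), tuple(b)))
        allowed.add((tuple(b), tuple(a)))
    leaks = []
    for axis in range(z.ndim):
        lo = tuple(slice(0, -1) if a == axis else slice(None) for a in range(z.ndim))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(z.ndim))
        pair = ((z[lo] == Zone.INTERIOR) & (z[hi] == Zone.EXTERIOR)) | (
            (z[lo] == Zone.EXTERIOR) & (z[hi] == Zone.INTERIOR)
        )
        for idx in zip(*np.nonzero(pair)):
            a = tuple(idx)
            b = tuple(idx[k] + (1 if k == axis else 0) for k in range(z.ndim))
            if (a, b) not in allowed:
                leaks.append((a, b))
    return leaks


def porous_cells_have_fluid_contact(zones: ZoneMap) -> bool:
    """Every porous cell reaches interior and exterior fluid via face steps
    through porous cells (the layer separates the two zones)."""
    z = zones.zone
    porous = z == Zone.POROUS
    if not porous.any():
        return True

    def reaches(target: int) -> np.ndarray:
        hit = np.zeros_like(porous)
        for axis in range(z.ndim):
            hit |= porous & (np.roll(z, 1, axis) == target) & _not_wrap(z.shape, axis, 1)
            hit |= porous & (np.roll(z, -1, axis) == target) & _not_wrap(z.shape, axis, -1)
        # propagate through the porous region
        changed = True
        while changed:
            grown = hit.copy()
            for axis in range(z.ndim):
                grown |= porous & np.roll(hit, 1, axis) & _not_wrap(z.shape, axis, 1)
                grown |= porous & np.roll(hit, -1, axis) & _not_wrap(z.shape, axis, -1)
            changed = bool((grown & ~hit).any())
            hit = grown
        return hit

    return bool(reaches(Zone.INTERIOR)[porous].all() and reaches(Zone.EXTERIOR)[porous].all())


def _not_wrap(shape, axis, shift) -> np.ndarray:
    mask = np.ones(shape, dtype=bool)
    sl = [slice(None)] * len(shape)
    sl[axis] = 0 if shift == 1 else -1
    mask[tuple(sl)] = False
    return mask


# ---------------------------------------------------------------------------
# benchmark cases

BENCHMARKS = ("poiseuille_channel", "lid_cavity", "backward_step", "porous_plug")


def build_benchmark_case(
    name: str, resolution: tuple[int, int]
) -> tuple[StructuredGrid, ZoneMap, dict]:
    """Closed, solvable validation fixtures on uniform grids.

    Returns (grid, zones, boundary-value set).  The boundary-value set is a
    dict with keys among 'inlet_speed', 'inlet_profile' (w at the z_min face
    per x-cell), 'wall_velocity' (face name -> tangential speed) and
    'reference' (closed-form quantities for the case).
    """
    if name not in BENCHMARKS:
        raise GeometryConfigError(
            f"unknown benchmark {name!r}; available: {', '.join(BENCHMARKS)}"
        )
    nx, nz = resolution
    if name == "poiseuille_channel":
        H, L = 0.02, 0.08
        grid = StructuredGrid((np.full(nx, H / nx), np.full(nz, L / nz)))
        zone = np.full(grid.shape, int(Zone.INTERIOR))
        boundary = {
            "x_min": BoundaryTag.NOSLIP_WALL,
            "x_max": BoundaryTag.NOSLIP_WALL,
            "z_min": BoundaryTag.VELOCITY_INLET,
            "z_max": BoundaryTag.PRESSURE_OUTLET,
        }
        u_mean = 5.0e-3  # Re ~ 100 on the gap for 20 C water
        xc = grid.centers(0)
        profile = 6.0 * u_mean * (xc / H) * (1 - xc / H)
        bvs = {
            "inlet_profile": profile,
            "inlet_speed": u_mean,
            "reference": {"H": H, "L": L, "u_mean": u_mean, "u_max": 1.5 * u_mean},
        }
        return grid, ZoneMap(zone=zone, boundary=boundary), bvs

    if name == "lid_cavity":
        H = 0.01
        grid = StructuredGrid((np.full(nx, H / nx), np.full(nz, H / nz)))
        zone = np.full(grid.shape, int(Zone.INTERIOR))
        boundary = {f: BoundaryTag.NOSLIP_WALL for f in ("x_min", "x_max", "z_min", "z_max")}
        bvs = {"wall_velocity": {"x_max": 0.01}, "reference": {"H": H, "u_lid": 0.01}}
        return grid, ZoneMap(zone=zone, boundary=boundary), bvs

    if name == "backward_step":
        H, L = 0.02, 0.24
        s = H / 2  # expansion ratio 2
        grid = StructuredGrid((np.full(nx, H / nx), np.full(nz, L / nz)))
        zone = np.full(grid.shape, int(Zone.INTERIOR))
        xc, zc = grid.centers(0), grid.centers(1)
        L_in = L / 6
        zone[np.ix_(xc < s, zc < L_in)] = Zone.SOLID
        boundary = {
            "x_min": BoundaryTag.NOSLIP_WALL,
            "x_max": BoundaryTag.NOSLIP_WALL,
            "z_min": BoundaryTag.VELOCITY_INLET,
            "z_max": BoundaryTag.PRESSURE_OUTLET,
        }
        u_mean = 5.0e-3
        profile = np.where(
            xc > s, 6.0 * u_mean * ((xc - s) / s) * (1 - (xc - s) / s), 0.0
        )
        bvs = {
            "inlet_profile": profile,
            "inlet_speed": u_mean,
            "reference": {"H": H, "step": s, "L_in": L_in, "u_mean": u_mean},
        }
        return grid, ZoneMap(zone=zone, boundary=boundary), bvs

    # porous_plug
    H, L = 0.02, 0.10
    grid = StructuredGrid((np.full(nx, H / nx), np.full(nz, L / nz)))
    zone = np.full(grid.shape, int(Zone.INTERIOR))
    zc = grid.centers(1)
    j0 = nz // 2
    plug = slice(j0, j0 + 1)  # one-cell slab spanning the section
    zone[:, plug] = Zone.POROUS
    zone[:, j0 + 1:] = Zone.EXTERIOR
    slot = np.full(grid.shape, -1)
    slot[:, plug] = 1
    boundary = {
        "x_min": BoundaryTag.SLIP_WALL,
        "x_max": BoundaryTag.SLIP_WALL,
        "z_min": BoundaryTag.VELOCITY_INLET,
        "z_max": BoundaryTag.PRESSURE_OUTLET,
    }
    bvs = {
        "inlet_speed": 0.183,
        "reference": {"H": H, "L": L, "plug_thickness": float(grid.spacings[1][j0]),
                      "z_plug": (float(grid.faces(1)[j0]), float(grid.faces(1)[j0 + 1]))},
    }
    return grid, ZoneMap(zone=zone, boundary=boundary, slot_id=slot), bvs
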