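"""Diagnostics of the solved cross-step flow field.

Covers the quantities used to characterise vortical cross-step filtration:
streamlines and dividing streamlines, vortex-core detection and confinement
classification (inside a slot vs outside the filter), per-slot outflow and
shear profiles, centreline velocity/pressure profiles, particle-exclusion
radii and zero-Stokes-number particle paths with wall sliding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiLineString, Point
from shapely.ops import nearest_points

from .geometry import StructuredGrid, Zone, ZoneMap
from .porous import FluidProperties
from .solver import FlowField, slot_outflow

__all__ = [
    "OutOfDomainError",
    "Streamline",
    "VortexCore",
    "SlotFluxProfile",
    "DividingStreamlineResult",
    "interpolate_velocity",
    "interpolate_pressure",
    "trace_streamline",
    "locate_vortex_cores",
    "slot_flux_profile",
    "centreline_profiles",
    "mouth_centre_probe",
    "find_dividing_streamline",
    "trace_particle_path",
    "reynolds_number",
]


class OutOfDomainError(ValueError):
    """Query point outside the fluid domain (or inside a solid cell)."""


# ---------------------------------------------------------------------------
# interpolation


def _bilinear(xs: np.ndarray, zs: np.ndarray, arr: np.ndarray, x: float, z: float) -> float:
    """Bilinear interpolation on a tensor grid with clamped extrapolation."""
    i = int(np.clip(np.searchsorted(xs, x) - 1, 0, len(xs) - 2))
    j = int(np.clip(np.searchsorted(zs, z) - 1, 0, len(zs) - 2))
    tx = np.clip((x - xs[i]) / (xs[i + 1] - xs[i]), 0.0, 1.0)
    tz = np.clip((z - zs[j]) / (zs[j + 1] - zs[j]), 0.0, 1.0)
    return float(
        (1 - tx) * (1 - tz) * arr[i, j]
        + tx * (1 - tz) * arr[i + 1, j]
        + (1 - tx) * tz * arr[i, j + 1]
        + tx * tz * arr[i + 1, j + 1]
    )


def _cell_of(grid: StructuredGrid, point) -> tuple[int, int]:
    xf, zf = grid.faces(0), grid.faces(1)
    x, z = point
    if not (xf[0] <= x <= xf[-1] and zf[0] <= z <= zf[-1]):
        raise OutOfDomainError(f"point {tuple(point)} outside the domain")
    i = int(np.clip(np.searchsorted(xf, x) - 1, 0, grid.shape[0] - 1))
    j = int(np.clip(np.searchsorted(zf, z) - 1, 0, grid.shape[1] - 1))
    return i, j


def interpolate_velocity(field: FlowField, point) -> np.ndarray:
    """Velocity vector (u, w) at a point, bilinear from the staggered data.

    Exact for fields linear in each coordinate.  Raises
    :class:`OutOfDomainError` for points outside the domain or in solid cells.
    """
    grid = field.grid
    i, j = _cell_of(grid, point)
    if field.zones.zone[i, j] == Zone.SOLID:
        raise OutOfDomainError(f"point {tuple(point)} lies in a solid cell")
    x, z = point
    u = _bilinear(grid.faces(0), grid.centers(1), field.u, x, z)
    w = _bilinear(grid.centers(0), grid.faces(1), field.w, x, z)
    return np.array([u, w])


def interpolate_pressure(field: FlowField, point) -> float:
    grid = field.grid
    i, j = _cell_of(grid, point)
    if field.zones.zone[i, j] == Zone.SOLID:
        raise OutOfDomainError(f"point {tuple(point)} lies in a solid cell")
    return _bilinear(grid.centers(0), grid.centers(1), field.p, point[0], point[1])


# ---------------------------------------------------------------------------
# streamlines


@dataclass
class Streamline:
    points: np.ndarray            # (n, 2)
    arc_length: float
    termination: str              # outlet | boundary | porous_exit | max_steps | stagnation
    slot: Optional[int] = None    # slot id if terminated in a porous layer

    def as_linestring(self) -> LineString:
        return LineString(self.points)


VelocityFn = Callable[[np.ndarray], np.ndarray]


def _clip_to_bounds(p0: np.ndarray, p1: np.ndarray, bounds) -> np.ndarray:
    """Shorten the segment p0 -> p1 to end on the first domain boundary hit."""
    x0, x1, z0, z1 = bounds
    t = 1.0
    d = p1 - p0
    for coord, lo, hi in ((0, x0, x1), (1, z0, z1)):
        if d[coord] > 0 and p1[coord] > hi:
            t = min(t, (hi - p0[coord]) / d[coord])
        elif d[coord] < 0 and p1[coord] < lo:
            t = min(t, (lo - p0[coord]) / d[coord])
    return p0 + max(t, 0.0) * d


def _velocity_fn(field: Union[FlowField, VelocityFn]):
    if isinstance(field, FlowField):
        grid = field.grid

        def vf(pt):
            return interpolate_velocity(field, pt)

        bounds = (0.0, grid.faces(0)[-1], 0.0, grid.faces(1)[-1])
        return vf, bounds, field
    return field, None, None


def trace_streamline(
    field: Union[FlowField, VelocityFn],
    seed,
    max_step: Optional[float] = None,
    max_steps: int = 50_000,
    bounds: Optional[tuple] = None,
    stop: Optional[Callable[[np.ndarray], Optional[str]]] = None,
) -> Streamline:
    """Integrate the steady velocity field from a seed (4th-order Runge-Kutta).

    The step is adaptive: at most half the local cell size (or ``max_step``
    for callable fields).  Termination reasons: 'outlet' (crossed the
    downstream pressure outlet), 'boundary' (left the domain laterally or met
    a solid cell), 'porous_exit' (entered a porous cell; ``slot`` records
    which), 'max_steps', or 'stagnation' for a zero-velocity seed.
    """
    vf, fbounds, ff = _velocity_fn(field)
    bounds = bounds or fbounds
    if bounds is None:
        raise ValueError("bounds required for callable velocity fields")
    x0, x1, z0, z1 = bounds

    def local_step(pt) -> float:
        if ff is not None:
            i, j = _cell_of(ff.grid, pt)
            return 0.5 * min(ff.grid.spacings[0][i], ff.grid.spacings[1][j])
        return max_step or 0.01 * max(x1 - x0, z1 - z0)

    pt = np.asarray(seed, dtype=float)
    pts = [pt.copy()]
    arc = 0.0
    termination = "max_steps"
    slot = None
    v = np.asarray(vf(pt), float)
    if np.linalg.norm(v) < 1e-14:
        return Streamline(points=np.array(pts), arc_length=0.0, termination="stagnation")

    for _ in range(max_steps):
        speed = np.linalg.norm(v)
        if speed < 1e-12:
            termination = "stagnation"
            break
        ds = local_step(pt)
        dt = ds / speed

        def rhs(q):
            try:
                return np.asarray(vf(q), float)
            except OutOfDomainError:
                return v  # frozen velocity just outside; the position test ends the trace

        k1 = rhs(pt)
        k2 = rhs(pt + 0.5 * dt * k1)
        k3 = rhs(pt + 0.5 * dt * k2)
        k4 = rhs(pt + dt * k3)
        new = pt + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

        if stop is not None:
            reason = stop(new)
            if reason:
                pts.append(new)
                arc += np.linalg.norm(new - pt)
                termination = reason
                break
        if new[1] >= z1 or not (x0 <= new[0] <= x1 and z0 <= new[1]):
            new = _clip_to_bounds(pt, new, bounds)
            termination = "outlet" if new[1] >= z1 * (1 - 1e-12) else "boundary"
            pts.append(new)
            arc += np.linalg.norm(new - pt)
            break
        if ff is not None:
            i, j = _cell_of(ff.grid, new)
            zc = ff.zones.zone[i, j]
            if zc == Zone.SOLID:
                termination = "boundary"
                pts.append(new)
                arc += np.linalg.norm(new - pt)
                break
            if zc == Zone.POROUS:
                termination = "porous_exit"
                slot = int(ff.zones.slot_id[i, j]) if ff.zones.slot_id[i, j] > 0 else None
                pts.append(new)
                arc += np.linalg.norm(new - pt)
                break
        arc += np.linalg.norm(new - pt)
        pt = new
        pts.append(pt.copy())
        try:
            v = np.asarray(vf(pt), float)
        except OutOfDomainError:
            termination = "boundary"
            break
    return Streamline(points=np.array(pts), arc_length=arc, termination=termination, slot=slot)


# ---------------------------------------------------------------------------
# vortex cores


@dataclass
class VortexCore:
    position: np.ndarray
    swirl_strength: float      # s^-1, imaginary part of velocity-gradient eigenvalue
    in_slot: bool
    slot: Optional[int]
    axial_velocity: float      # velocity along the slot/helix axis; NaN in planar mode


def _classify_core(zones: ZoneMap, pos) -> tuple[bool, Optional[int]]:
    """Inside a slot means between the rib crest and the porous floor; the
    layer itself (and anything beyond it) counts as outside the filter."""
    lay = zones.layout
    if lay is None:
        return False, None
    x, z = pos
    r_out = float(lay.outer_radius(z))
    for k, (a, b) in enumerate(lay.slot_spans, start=1):
        if a <= z <= b and (r_out - lay.params.step_height) <= x < r_out:
            return True, k
    return False, None


def streamfunction(field: FlowField) -> np.ndarray:
    """Cell-centred streamfunction from the axial velocity.

    Planar mode: psi = int w dx; axisymmetric mode: Stokes streamfunction
    psi = int w r dr.  Solid cells contribute nothing, so closed
    recirculation regions appear as interior extrema.
    """
    grid = field.grid
    dx = grid.spacings[0]
    wc = field.cell_velocity()[1]
    fluidm = field.zones.zone != Zone.SOLID
    wcm = np.where(fluidm, wc, 0.0)
    weight = dx[:, None]
    if grid.mode == "axisymmetric":
        weight = (grid.centers(0) * dx)[:, None]
    # cumulative sum lands on the outer cell face; shift back half a cell
    return np.cumsum(wcm * weight, axis=0) - 0.5 * wcm * weight


def swirling_strength(field: FlowField) -> np.ndarray:
    """Cell-centred 2-D swirling strength lambda_ci (s^-1)."""
    grid = field.grid
    uc, wc = field.cell_velocity()
    xc, zc = grid.centers(0), grid.centers(1)
    fluidm = field.zones.zone != Zone.SOLID
    ucm = np.where(fluidm, uc, 0.0)
    wcm = np.where(fluidm, wc, 0.0)
    du_dx = np.gradient(ucm, xc, axis=0)
    du_dz = np.gradient(ucm, zc, axis=1)
    dw_dx = np.gradient(wcm, xc, axis=0)
    dw_dz = np.gradient(wcm, zc, axis=1)
    tr_half = 0.5 * (du_dx + dw_dz)
    det = du_dx * dw_dz - du_dz * dw_dx
    disc = det - tr_half**2
    lam = np.sqrt(np.maximum(disc, 0.0))
    return np.where(fluidm, lam, 0.0)


def locate_vortex_cores(
    field: FlowField,
    zones: ZoneMap,
    grid: StructuredGrid,
    rel_threshold: float = 0.3,
    abs_threshold: float = 1e-4,
    region: str = "filter",
) -> list[VortexCore]:
    """Vortex cores: interior streamfunction extrema with genuine swirl.

    A closed recirculation region in 2-D has a streamfunction extremum at
    its centre; shear layers, which carry high vorticity but no closed
    streamlines, are monotone in the streamfunction and are therefore
    excluded by construction.  Each candidate extremum must additionally
    carry swirling strength (the imaginary part of the velocity-gradient
    eigenvalue) above ``rel_threshold`` times the regional maximum and above
    ``abs_threshold`` (s^-1).  Returns an empty list for irrotational fields.

    ``region='filter'`` (cross-step layouts only) restricts the search to the
    slot neighbourhood — axially from the anterior edge of slot 1 to the
    closed back, radially from just below the rib crests to three step
    heights beyond the porous floor.  That is the band the confinement
    diagnostic examines; it excludes the mouth-lip shear layer and the wake
    behind the model.  ``region='all'`` searches the whole fluid domain.
    """
    lam = swirling_strength(field)
    if lam.max() <= abs_threshold:
        return []
    nx, nz = lam.shape
    xc, zc = grid.centers(0), grid.centers(1)
    psi = streamfunction(field)
    fluidm = field.zones.zone != Zone.SOLID

    pad_hi = np.pad(psi, 1, constant_values=np.inf)
    pad_lo = np.pad(psi, 1, constant_values=-np.inf)
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    neigh_max = np.stack([pad_lo[1 + di:1 + di + nx, 1 + dj:1 + dj + nz]
                          for di, dj in shifts]).max(axis=0)
    neigh_min = np.stack([pad_hi[1 + di:1 + di + nx, 1 + dj:1 + dj + nz]
                          for di, dj in shifts]).min(axis=0)
    is_ext = ((psi > neigh_max) | (psi < neigh_min)) & fluidm
    is_ext[0, :] = is_ext[-1, :] = False
    is_ext[:, 0] = is_ext[:, -1] = False

    lay = zones.layout
    if region == "filter" and lay is not None:
        zz = zc[None, :] * np.ones((nx, 1))
        xx = xc[:, None] * np.ones((1, nz))
        r_out = lay.outer_radius(zz)
        band = (
            (zz >= lay.slot_spans[0][0]) & (zz <= lay.z_back)
            & (xx >= r_out - 1.5 * lay.params.step_height)
            & (xx <= r_out + 3.0 * lay.params.step_height)
        )
        is_ext &= band
        lam_ref = lam[band & fluidm].max() if np.any(band & fluidm) else lam.max()
    else:
        lam_ref = lam.max()
    thr = max(rel_threshold * lam_ref, abs_threshold)

    cores: list[VortexCore] = []
    for i, j in zip(*np.nonzero(is_ext)):
        if lam[i, j] <= thr:
            continue
        pos = np.array([xc[i], zc[j]])
        in_slot, slot = _classify_core(zones, pos)
        cores.append(VortexCore(
            position=pos, swirl_strength=float(lam[i, j]),
            in_slot=in_slot, slot=slot,
            axial_velocity=float("nan"),
        ))
    cores.sort(key=lambda c: -c.swirl_strength)
    return cores


# ---------------------------------------------------------------------------
# slot flux / shear profiles


@dataclass
class SlotFluxProfile:
    slot: int
    stations_z: np.ndarray          # axial station centres (m)
    outflow: np.ndarray             # volume flux per station (m^3/s)
    thirds: tuple[float, float, float]  # anterior/middle/posterior fractions
    total_outflow: float
    shear_stress: np.ndarray        # Pa, on the medial porous surface
    tangential_velocity: np.ndarray  # z-velocity one cell medial of the layer


def slot_flux_profile(field: FlowField, zones: ZoneMap, slot: int) -> SlotFluxProfile:
    """Per-station outflow, shear and near-layer tangential velocity of a slot.

    Stations are the axial grid columns of the slot's porous strip; thirds
    are equal arc-length divisions of the slot axis from anterior to
    posterior edge.
    """
    if not np.any(zones.slot_id == slot):
        raise ValueError(f"no porous cells carry slot id {slot}")
    grid = field.grid
    d_Au = grid.face_areas_x()
    d_Aw = grid.face_areas_z()
    mu = field.bvs.get("viscosity", 1.003e-3)
    cols = sorted(set(j for _, j in zip(*np.nonzero(zones.slot_id == slot))))
    zc = grid.centers(1)
    xc = grid.centers(0)
    qs, taus, wts, zs = [], [], [], []
    uc, wc = field.cell_velocity()
    for j in cols:
        is_ = [i for i in np.nonzero(zones.slot_id[:, j] == slot)[0]]
        q = 0.0
        for i in is_:
            if i + 1 == grid.shape[0] or zones.zone[i + 1, j] == Zone.EXTERIOR:
                q += field.u[i + 1, j] * d_Au[i + 1, j]
            if j + 1 < grid.shape[1] and zones.zone[i, j + 1] == Zone.EXTERIOR:
                q += field.w[i, j + 1] * d_Aw[i, j + 1]
            if j - 1 >= 0 and zones.zone[i, j - 1] == Zone.EXTERIOR:
                q -= field.w[i, j] * d_Aw[i, j]
        i_med = min(is_) - 1  # cell on the interior (medial) side of the layer
        if i_med >= 1 and zones.zone[i_med, j] == Zone.INTERIOR:
            dw = wc[i_med, j] - wc[min(is_), j]
            taus.append(mu * dw / (xc[min(is_)] - xc[i_med]))
            wts.append(wc[i_med, j])
        else:
            taus.append(np.nan)
            wts.append(np.nan)
        qs.append(q)
        zs.append(zc[j])
    zs = np.array(zs); qs = np.array(qs)
    lay = zones.layout
    if lay is not None and 1 <= slot <= len(lay.slot_spans):
        a, b = lay.slot_spans[slot - 1]
    else:
        a, b = zs.min(), zs.max()
    frac_pos = np.clip((zs - a) / max(b - a, 1e-30), 0.0, 1.0 - 1e-12)
    total = float(qs.sum())
    thirds = tuple(
        float(qs[(frac_pos >= lo) & (frac_pos < hi)].sum() / total) if total != 0 else 0.0
        for lo, hi in ((0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0))
    )
    return SlotFluxProfile(
        slot=slot, stations_z=zs, outflow=qs, thirds=thirds, total_outflow=total,
        shear_stress=np.array(taus), tangential_velocity=np.array(wts),
    )


# ---------------------------------------------------------------------------
# centreline profiles and probes


def centreline_profiles(field: FlowField) -> pd.DataFrame:
    """v_z(z) and p(z) on the model centreline (x = 0), one row per cell."""
    grid = field.grid
    uc, wc = field.cell_velocity()
    zc = grid.centers(1)
    df = pd.DataFrame({"z_m": zc, "v_z_m_per_s": wc[0, :], "p_Pa": field.p[0, :]})
    solid = field.zones.zone[0, :] == Zone.SOLID
    df.loc[solid, ["v_z_m_per_s", "p_Pa"]] = np.nan
    return df


def mouth_centre_probe(field: FlowField) -> tuple[float, float]:
    """(axial velocity, gauge pressure) at the centre of the mouth aperture."""
    lay = field.zones.layout
    if lay is None:
        raise ValueError("mouth probe needs a cross-step layout")
    pt = (float(field.grid.centers(0)[0]), lay.z_mouth)
    v = interpolate_velocity(field, pt)[1]
    p = interpolate_pressure(field, pt)
    return float(v), float(p)


def filter_centre_probe(field: FlowField) -> tuple[float, float]:
    """Probe 30 mm posterior of the mouth-aperture centre (filter centre)."""
    lay = field.zones.layout
    if lay is None:
        raise ValueError("filter probe needs a cross-step layout")
    pt = (float(field.grid.centers(0)[0]), lay.z_mouth + 0.030)
    return float(interpolate_velocity(field, pt)[1]), float(interpolate_pressure(field, pt))


# ---------------------------------------------------------------------------
# dividing streamlines


@dataclass
class DividingStreamlineResult:
    slot: int
    seed_offset: float                 # transverse seed coordinate (m)
    streamline: Optional[Streamline]
    min_distance: float                # to the interior filter surface (m)
    exclusion_radius: float            # = min_distance by definition
    bracket: tuple[float, float]
    found: bool = True


def interior_surface(zones: ZoneMap, grid: StructuredGrid) -> MultiLineString:
    """The interior filter surface: faces between interior fluid and
    solid/porous cells, as a shapely multiline in (x, z)."""
    xf, zf = grid.faces(0), grid.faces(1)
    z = zones.zone
    segs = []
    nx, nz = z.shape
    for i in range(nx):
        for j in range(nz):
            if z[i, j] != Zone.INTERIOR:
                continue
            if i + 1 < nx and z[i + 1, j] in (Zone.SOLID, Zone.POROUS):
                segs.append(((xf[i + 1], zf[j]), (xf[i + 1], zf[j + 1])))
            if i - 1 >= 0 and z[i - 1, j] in (Zone.SOLID, Zone.POROUS):
                segs.append(((xf[i], zf[j]), (xf[i], zf[j + 1])))
            if j + 1 < nz and z[i, j + 1] in (Zone.SOLID, Zone.POROUS):
                segs.append(((xf[i], zf[j + 1]), (xf[i + 1], zf[j + 1])))
            if j - 1 >= 0 and z[i, j - 1] in (Zone.SOLID, Zone.POROUS):
                segs.append(((xf[i], zf[j]), (xf[i + 1], zf[j])))
    if not segs:
        raise ValueError("zone map has no interior filter surface")
    return MultiLineString(segs)


def _min_distance(surface, points: np.ndarray) -> float:
    pts = shapely.points(points)
    return float(np.min(shapely.distance(surface, pts)))


def bisect_dividing_seed(
    trace: Callable[[float], object],
    enters: Callable[[object], bool],
    lo: float,
    hi: float,
    tol: float,
) -> tuple[float, float]:
    """Bisection on a transverse seed coordinate.

    ``lo`` must classify as 'continues' and ``hi`` as 'enters'; returns the
    final (lo, hi) bracket with hi - lo <= tol.  Raises ValueError if the
    endpoints do not bracket a transition.
    """
    s_lo, s_hi = trace(lo), trace(hi)
    if enters(s_lo) or not enters(s_hi):
        raise ValueError(
            f"seeds do not bracket a dividing streamline: "
            f"lo={lo} enters={enters(s_lo)}, hi={hi} enters={enters(s_hi)}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if enters(trace(mid)):
            hi = mid
        else:
            lo = mid
    return lo, hi


def find_dividing_streamline(
    field: FlowField,
    slot: int,
    tol: float = 1e-5,
) -> DividingStreamlineResult:
    """Dividing streamline for one slot of the solved cross-step model.

    Seeds are placed on the mouth-aperture plane; the transverse coordinate
    is bisected between a streamline that continues past the slot (medial)
    and one that exits through slot <= ``slot`` (lateral).  A streamline
    that terminates on a rib crest counts as 'continues', which is
    conservative toward larger exclusion radii.

    The exclusion radius is the minimum distance from the dividing
    streamline to the interior filter surface over its approach path — from
    the mouth plane up to the slot's anterior edge, i.e. the tightest
    clearance past the mouth rim and the rib crests a particle must pass to
    reach the slot entrance.  (The terminal graze at the separation corner
    itself shrinks with the bisection tolerance and carries no physical
    information, so it is excluded.)

    If the slot has no outflow (or even the centreline streamline enters
    slot <= ``slot``), a sentinel result with ``found=False`` is returned.
    """
    lay = field.zones.layout
    if lay is None:
        raise ValueError("dividing streamlines need a cross-step layout")
    if slot_outflow(field, field.grid, field.zones, slot) <= 0:
        return DividingStreamlineResult(
            slot=slot, seed_offset=float("nan"), streamline=None,
            min_distance=float("nan"), exclusion_radius=float("nan"),
            bracket=(float("nan"), float("nan")), found=False,
        )
    grid = field.grid
    zc = grid.centers(1)
    # seed just upstream of the mouth plane, in the approaching flow
    j_mouth = int(np.searchsorted(zc, lay.z_mouth))
    z_seed = zc[max(j_mouth - 1, 0)]
    r_ap = float(lay.rib_inner_radius(lay.z_mouth))
    surface = interior_surface(field.zones, grid)

    def trace(x_seed: float) -> Streamline:
        return trace_streamline(field, (x_seed, z_seed))

    def enters(s: Streamline) -> bool:
        return s.termination == "porous_exit" and s.slot is not None and s.slot <= slot

    x_lo = float(grid.centers(0)[0])
    x_hi = r_ap - 0.25 * grid.spacings[0][0]
    if enters(trace(x_lo)):
        return DividingStreamlineResult(
            slot=slot, seed_offset=x_lo, streamline=trace(x_lo),
            min_distance=float("nan"), exclusion_radius=float("nan"),
            bracket=(x_lo, x_lo), found=False,
        )
    lo, hi = bisect_dividing_seed(trace, enters, x_lo, x_hi, tol)
    s = trace(hi)
    approach = s.points[s.points[:, 1] <= lay.slot_spans[slot - 1][0]]
    if len(approach) == 0:
        approach = s.points[:1]
    dist = _min_distance(surface, approach)
    return DividingStreamlineResult(
        slot=slot, seed_offset=hi, streamline=s,
        min_distance=dist, exclusion_radius=dist, bracket=(lo, hi),
    )


# ---------------------------------------------------------------------------
# particle paths (Stokes number 0, no rebound)


@dataclass
class ParticlePath:
    points: np.ndarray
    fate: str            # entered_slot_k | excluded_past_slot_k | reached_back | exited | stalled
    contact: np.ndarray  # bool per point: at standoff from a boundary


def trace_particle_path(
    field: Union[FlowField, VelocityFn],
    radius: float,
    start,
    surface=None,
    bounds: Optional[tuple] = None,
    max_steps: int = 50_000,
) -> ParticlePath:
    """Path of a spherical particle advected with the local flow velocity.

    The particle centre follows the fluid (Stokes number 0); when it comes
    within ``radius`` of a boundary surface it is projected back to the
    standoff distance (sliding without elastic rebound).  For a
    :class:`FlowField` the surface is the union of solid and porous cell
    boundaries of the filter; a shapely geometry can be passed for
    constructed cases.

    Fate: 'entered_slot_k' when the centre enters slot k's groove,
    'excluded_past_slot_k' when it passed slot k in wall contact without
    entering, 'reached_back' near the closed posterior wall, 'exited' when
    leaving the domain, 'stalled' when progress stops while in contact.
    """
    if radius < 0:
        raise ValueError("particle radius must be >= 0")
    if radius == 0 and isinstance(field, FlowField):
        s = trace_streamline(field, start)
        fate = {"porous_exit": f"entered_slot_{s.slot}" if s.slot else "entered_slot",
                "outlet": "exited", "boundary": "exited",
                "max_steps": "stalled", "stagnation": "stalled"}[s.termination]
        return ParticlePath(points=s.points, fate=fate,
                            contact=np.zeros(len(s.points), dtype=bool))

    vf, fbounds, ff = _velocity_fn(field)
    bounds = bounds or fbounds
    if bounds is None:
        raise ValueError("bounds required for callable velocity fields")
    x0, x1, z0, z1 = bounds
    if surface is None:
        if ff is None:
            raise ValueError("surface geometry required for callable fields")
        surface = _contact_surface(ff.zones, ff.grid)
    lay = ff.zones.layout if ff is not None else None

    pt = np.asarray(start, dtype=float)
    if float(shapely.distance(surface, Point(pt))) < radius:
        raise ValueError("start position is closer to a boundary than the particle radius")

    pts = [pt.copy()]
    contact = [False]
    last_contact_slot = None
    passed_in_contact: Optional[int] = None
    fate = "stalled"
    stall_ref = pt.copy()
    stall_count = 0
    for step in range(max_steps):
        try:
            v = np.asarray(vf(pt), float)
        except OutOfDomainError:
            fate = "exited"
            break
        speed = np.linalg.norm(v)
        if ff is not None:
            i, j = _cell_of(ff.grid, pt)
            h = 0.25 * min(ff.grid.spacings[0][i], ff.grid.spacings[1][j])
        else:
            h = 0.02 * max(x1 - x0, z1 - z0)
        if speed < 1e-12:
            fate = "stalled"
            break
        new = pt + v / speed * min(h, radius if radius > 0 else h)
        dist = float(shapely.distance(surface, Point(new)))
        touching = dist < radius
        wedged = False
        if touching and dist > 1e-15:
            # project back to the standoff distance; with several nearby
            # walls iterate — if no feasible position exists (throat
            # narrower than 2 r) the particle cannot advance
            for _ in range(8):
                near = nearest_points(surface, Point(new))[0]
                nvec = new - np.array([near.x, near.y])
                nn = np.linalg.norm(nvec)
                if nn < 1e-15:
                    break
                new = np.array([near.x, near.y]) + nvec / nn * radius
                dist = float(shapely.distance(surface, Point(new)))
                if dist >= radius * (1 - 1e-9):
                    break
            else:
                wedged = True
            if dist < radius * (1 - 1e-6):
                wedged = True
        if wedged:
            new = pt  # no feasible advance; stall detection will conclude
        if not (x0 <= new[0] <= x1 and z0 <= new[1] <= z1):
            fate = "exited"
            pts.append(new); contact.append(touching)
            break
        pt = new
        pts.append(pt.copy())
        contact.append(touching)

        if lay is not None:
            in_slot, k = _classify_core(ff.zones, pt)
            if in_slot:
                fate = f"entered_slot_{k}"
                break
            if pt[1] >= lay.z_back - 0.5 * lay.params.rib_width:
                fate = "reached_back"
                break
            if touching:
                for kk, (a, b) in enumerate(lay.slot_spans, start=1):
                    if a <= pt[1] <= b:
                        last_contact_slot = kk
            if last_contact_slot is not None and pt[1] > lay.slot_spans[last_contact_slot - 1][1]:
                passed_in_contact = last_contact_slot
        # stall detection: no net progress over many steps
        stall_count += 1
        if stall_count >= 200:
            if np.linalg.norm(pt - stall_ref) < 0.5 * h:
                fate = "stalled" if passed_in_contact is None else \
                    f"excluded_past_slot_{passed_in_contact}"
                if lay is None and contact[-1]:
                    fate = "excluded"
                break
            stall_ref = pt.copy()
            stall_count = 0
    else:
        fate = "stalled"
    if fate == "stalled" and passed_in_contact is not None:
        fate = f"excluded_past_slot_{passed_in_contact}"
    if fate == "stalled" and lay is None and contact[-1]:
        fate = "excluded"
    return ParticlePath(points=np.array(pts), fate=fate, contact=np.array(contact))


def _contact_surface(zones: ZoneMap, grid: StructuredGrid) -> MultiLineString:
    """Boundaries a particle cannot cross: faces between plain fluid and
    solid-or-porous cells (the mesh stops particles but passes water)."""
    xf, zf = grid.faces(0), grid.faces(1)
    z = zones.zone
    nx, nz = z.shape
    blocked = (z == Zone.SOLID) | (z == Zone.POROUS)
    segs = []
    for i in range(nx):
        for j in range(nz):
            if blocked[i, j]:
                continue
            if i + 1 < nx and blocked[i + 1, j]:
                segs.append(((xf[i + 1], zf[j]), (xf[i + 1], zf[j + 1])))
            if i - 1 >= 0 and blocked[i - 1, j]:
                segs.append(((xf[i], zf[j]), (xf[i], zf[j + 1])))
            if j + 1 < nz and blocked[i, j + 1]:
                segs.append(((xf[i], zf[j + 1]), (xf[i + 1], zf[j + 1])))
            if j - 1 >= 0 and blocked[i, j - 1]:
                segs.append(((xf[i], zf[j]), (xf[i + 1], zf[j])))
    return MultiLineString(segs)


# ---------------------------------------------------------------------------


def reynolds_number(speed: float, hydraulic_diameter: float,
                    fluid: FluidProperties) -> float:
    """Re = rho * v * D / mu for an internal flow."""
    if speed <= 0 or hydraulic_diameter <= 0:
        raise ValueError("speed and hydraulic diameter must be positive")
    return fluid.density * speed * hydraulic_diameter / fluid.viscosity
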