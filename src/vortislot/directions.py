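"""Main-permeability direction mapping for irregular porous layers.

The porous layer of a cross-step filter is part of a tapered cone, so no
simple formula gives its surface normal per cell.  The mapping used here
solves a scalar boundary-value problem: the interior-water zone is held at
0, the exterior-water zone at 1, and the discrete Laplace equation is solved
on the porous cells.  The normalized gradient of the solved scalar in each
porous cell is the main (through-layer) permeability direction, oriented
from interior to exterior water.

The linear system is solved directly to a tight residual rather than for a
fixed iteration count, which makes the result mesh-independent for thin
layers.  The fixed zone values 0/1 are arbitrary: any strictly ordered pair
yields the same directions after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import StructuredGrid, Zone, ZoneMap

INTERIOR_VALUE = 0.0
EXTERIOR_VALUE = 1.0


class EmptyZoneError(ValueError):
    """No porous cells in the zone map."""


class TopologyError(ValueError):
    """A porous cell has no connection to the bounding fluid zones."""


class DegenerateGradientError(ValueError):
    """The solved scalar has (numerically) zero gradient in a porous cell."""


@dataclass
class ScalarZoneField:
    """Zone scalar: fixed 0/1 on fluid zones, solved on porous, NaN on solid."""

    values: np.ndarray
    residual: float


@dataclass
class DirectionField:
    """Unit main-permeability vectors per porous cell.

    vectors : array of shape (ndim,) + grid.shape; NaN outside porous cells
    """

    vectors: np.ndarray

    def at(self, idx: tuple[int, ...]) -> np.ndarray:
        return self.vectors[(slice(None),) + idx]


def _neighbor_offsets(ndim: int):
    for axis in range(ndim):
        for step in (-1, 1):
            off = [0] * ndim
            off[axis] = step
            yield axis, step, tuple(off)


def _face_weight(grid: StructuredGrid, axis: int, idx: tuple[int, ...],
                 nb: tuple[int, ...]) -> float:
    """Conductance A/d of the face between cells idx and nb (nb = idx +- 1 on axis)."""
    d = 0.5 * (grid.spacings[axis][idx[axis]] + grid.spacings[axis][nb[axis]])
    area = 1.0
    for a in range(grid.ndim):
        if a != axis:
            area *= grid.spacings[a][idx[a]]
    if grid.mode == "axisymmetric":
        if axis == 0:  # constant-r face at the shared radius
            f = grid.faces(0)
            area *= 2.0 * np.pi * f[max(idx[0], nb[0])]
        else:
            area *= 2.0 * np.pi * grid.centers(0)[idx[0]]
    return area / d


def solve_zone_scalar(grid: StructuredGrid, zones: ZoneMap,
                      rtol: float = 1e-12) -> ScalarZoneField:
    """Solve the discrete Laplace equation on the porous cells.

    Interior water is fixed at 0, exterior water at 1; solid faces are
    no-flux.  Raises :class:`EmptyZoneError` if there are no porous cells and
    :class:`TopologyError` naming the first porous cell that touches no fluid
    zone through the porous region.
    """
    zone = zones.zone
    porous_idx = list(zip(*np.nonzero(zone == Zone.POROUS)))
    if not porous_idx:
        raise EmptyZoneError("zone map contains no porous cells")
    unknown = {idx: k for k, idx in enumerate(porous_idx)}
    n = len(unknown)

    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = np.zeros(n)
    touches_fluid = np.zeros(n, dtype=bool)
    shape = zone.shape
    for idx, k in unknown.items():
        for axis, step, off in _neighbor_offsets(zone.ndim):
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                continue  # domain boundary: no-flux
            zt = zone[nb]
            if zt == Zone.SOLID:
                continue  # no-flux
            w = _face_weight(grid, axis, idx, nb)
            diag[k] += w
            if zt == Zone.POROUS:
                rows.append(k)
                cols.append(unknown[nb])
                vals.append(-w)
            elif zt == Zone.INTERIOR:
                rhs[k] += w * INTERIOR_VALUE
                touches_fluid[k] = True
            else:
                rhs[k] += w * EXTERIOR_VALUE
                touches_fluid[k] = True

    # every porous connected component must touch a fluid zone somewhere
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    n_comp, labels = sp.csgraph.connected_components(adj, directed=False)
    for comp in range(n_comp):
        members = np.nonzero(labels == comp)[0]
        if not touches_fluid[members].any():
            bad = porous_idx[members[0]]
            raise TopologyError(
                f"porous cell {tuple(int(c) for c in bad)} has no connection to a fluid zone"
            )

    A = sp.coo_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(n)]), np.concatenate([cols, np.arange(n)]))),
        shape=(n, n),
    ).tocsc()
    phi = spla.spsolve(A, rhs)
    residual = float(np.max(np.abs(A @ phi - rhs)) / max(np.max(np.abs(rhs)), 1.0))
    if residual > max(rtol, 1e-9):
        raise RuntimeError(f"zone-scalar solve residual {residual:.3e} above tolerance")

    values = np.full(shape, np.nan)
    values[zone == Zone.INTERIOR] = INTERIOR_VALUE
    values[zone == Zone.EXTERIOR] = EXTERIOR_VALUE
    for idx, k in unknown.items():
        values[idx] = phi[k]
    return ScalarZoneField(values=values, residual=residual)


def compute_directions(scalar: ScalarZoneField, grid: StructuredGrid,
                       zones: ZoneMap) -> DirectionField:
    """Per-porous-cell unit gradient of the zone scalar (interior->exterior).

    The gradient is a weighted least-squares fit over face-neighbor
    differences (fluid-zone fixed values serve as boundary data); on uniform
    Cartesian interiors this reduces to central differences.  Raises
    :class:`DegenerateGradientError` if a porous cell has gradient magnitude
    below 1e-12.
    """
    zone = zones.zone
    ndim = zone.ndim
    centers = [grid.centers(a) for a in range(ndim)]
    vec = np.full((ndim,) + zone.shape, np.nan)
    for idx in zip(*np.nonzero(zone == Zone.POROUS)):
        AtA = np.zeros((ndim, ndim))
        Atb = np.zeros(ndim)
        phi0 = scalar.values[idx]
        for axis, step, off in _neighbor_offsets(ndim):
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(c < 0 or c >= s for c, s in zip(nb, zone.shape)):
                continue
            if zone[nb] == Zone.SOLID:
                continue
            d = np.zeros(ndim)
            d[axis] = centers[axis][nb[axis]] - centers[axis][idx[axis]]
            w = 1.0 / np.dot(d, d)
            dphi = scalar.values[nb] - phi0
            AtA += w * np.outer(d, d)
            Atb += w * dphi * d
        try:
            g = np.linalg.solve(AtA, Atb)
        except np.linalg.LinAlgError:
            # rank-deficient stencil (e.g. 1-cell layer between walls):
            # fall back to the pseudo-inverse gradient
            g = np.linalg.lstsq(AtA, Atb, rcond=None)[0]
        norm = float(np.linalg.norm(g))
        if norm < 1e-12:
            raise DegenerateGradientError(
                f"zero scalar gradient in porous cell {tuple(int(c) for c in idx)}"
            )
        vec[(slice(None),) + idx] = g / norm
    return DirectionField(vectors=vec)


def map_permeability_directions(grid: StructuredGrid, zones: ZoneMap) -> DirectionField:
    """Convenience: solve the zone scalar and return the direction field."""
    return compute_directions(solve_zone_scalar(grid, zones), grid, zones)
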