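"""File output: legacy-ASCII VTK rectilinear grids, CSV tables, JSON
summaries and a checksummed manifest.

All outputs are deterministic (no timestamps), so re-running an identical
configuration reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np

from .geometry import StructuredGrid, Zone, ZoneMap
from .solver import ConvergenceReport, FlowField, slot_outflow


def write_vtk_rectilinear(path, grid: StructuredGrid,
                          cell_data: Optional[dict] = None,
                          cell_vectors: Optional[dict] = None) -> Path:
    """Write a 2-D structured grid as a legacy-ASCII VTK rectilinear file.

    ``cell_data`` maps names to (nx, nz) scalar arrays; ``cell_vectors`` to
    (2, nx, nz) or (3, nx, nz) arrays (z-padded to 3 components: VTK's
    x,y,z = our x, out-of-plane, z).
    """
    path = Path(path)
    xf, zf = grid.faces(0), grid.faces(1)
    nx, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "vortislot field",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx + 1} 2 {nz + 1}",
        f"X_COORDINATES {nx + 1} double",
        " ".join(f"{v:.9g}" for v in xf),
        "Y_COORDINATES 2 double",
        "0 1",
        f"Z_COORDINATES {nz + 1} double",
        " ".join(f"{v:.9g}" for v in zf),
    ]
    n_cells = nx * 1 * nz
    if cell_data or cell_vectors:
        lines.append(f"CELL_DATA {n_cells}")
    for name, arr in (cell_data or {}).items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell order: x fastest, then y, then z
        flat = np.asarray(arr, float).T.reshape(-1)
        lines.extend(" ".join(f"{v:.9g}" for v in flat[k:k + 9])
                     for k in range(0, len(flat), 9))
    for name, arr in (cell_vectors or {}).items():
        arr = np.asarray(arr, float)
        if arr.shape[0] == 2:
            arr = np.stack([arr[0], np.zeros_like(arr[0]), arr[1]])
        lines.append(f"VECTORS {name} double")
        vx, vy, vz = (np.nan_to_num(a).T.reshape(-1) for a in arr)
        lines.extend(f"{a:.9g} {b:.9g} {c:.9g}" for a, b, c in zip(vx, vy, vz))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_streamlines_vtk(path, streamlines) -> Path:
    """Polyline VTK output for streamlines / particle paths (x, 0, z)."""
    path = Path(path)
    all_pts = [np.asarray(s.points, float) for s in streamlines]
    n_total = sum(len(p) for p in all_pts)
    lines = [
        "# vtk DataFile Version 3.0",
        "vortislot streamlines",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n_total} double",
    ]
    for pts in all_pts:
        lines.extend(f"{x:.9g} 0 {z:.9g}" for x, z in pts)
    size = sum(len(p) + 1 for p in all_pts)
    lines.append(f"LINES {len(all_pts)} {size}")
    offset = 0
    for pts in all_pts:
        lines.append(" ".join(map(str, [len(pts), *range(offset, offset + len(pts))])))
        offset += len(pts)
    path.write_text("\n".join(lines) + "\n")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(field: FlowField, report: ConvergenceReport,
                  diagnostics: Optional[dict], directory) -> list[dict]:
    """Write the standard output set for one solve and return the manifest.

    Files: VTK field (velocity, pressure, zone), convergence CSV, centreline
    CSV (if a centreline exists), JSON summary, and manifest.json listing
    every file with its SHA-256 checksum.
    """
    from . import postprocess

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    uc, wc = field.cell_velocity()
    written.append(write_vtk_rectilinear(
        directory / "field.vtk", field.grid,
        cell_data={"pressure": field.p, "zone": field.zones.zone.astype(float)},
        cell_vectors={"velocity": np.stack([uc, wc])},
    ))

    conv = report.to_frame()
    conv.insert(0, "iteration", np.arange(1, len(conv) + 1))
    conv.to_csv(directory / "convergence.csv", index=False)
    written.append(directory / "convergence.csv")

    summary: dict = {
        "converged": bool(report.converged),
        "iterations": int(report.iterations),
        "max_velocity_m_per_s": float(np.nanmax(np.hypot(uc, wc))),
    }
    if field.zones.layout is not None:
        prof = postprocess.centreline_profiles(field)
        prof.to_csv(directory / "centreline.csv", index=False)
        written.append(directory / "centreline.csv")
        v_m, p_m = postprocess.mouth_centre_probe(field)
        summary["mouth_centre_velocity_m_per_s"] = v_m
        summary["mouth_centre_pressure_Pa"] = p_m
        slots = sorted(int(s) for s in np.unique(field.zones.slot_id) if s > 0)
        summary["slot_outflow_m3_per_s"] = {
            str(s): slot_outflow(field, field.grid, field.zones, s) for s in slots
        }
        cores = postprocess.locate_vortex_cores(field, field.zones, field.grid)
        summary["vortex_cores"] = [
            {"x_m": float(c.position[0]), "z_m": float(c.position[1]),
             "swirl_per_s": c.swirl_strength, "in_slot": c.in_slot, "slot": c.slot}
            for c in cores
        ]
    if diagnostics:
        summary.update(diagnostics)
    (directory / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(directory / "summary.json")

    manifest = [
        {"path": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
        for p in written
    ]
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
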