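"""Output writers: legacy-VTK ASCII snapshots, HDF5 checkpoints, CSV records.

The VTK writers emit the plain-text legacy format (STRUCTURED_POINTS for
voxel fields, POLYDATA for surfaces and tracer clouds), readable by
ParaView/VisIt without any VTK library dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np


def write_vtk_image(
    path: str | Path,
    origin: np.ndarray,
    spacing: float,
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
) -> Path:
    """Legacy-VTK STRUCTURED_POINTS file with point data (ASCII)."""
    scalars = scalars or {}
    vectors = vectors or {}
    arr = next(iter(scalars.values()), None)
    if arr is None:
        arr = next(iter(vectors.values()))[..., 0]
    nx, ny, nz = arr.shape
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\ngastroflow snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.6g} {origin[1]:.6g} {origin[2]:.6g}\n")
        fh.write(f"SPACING {spacing:.6g} {spacing:.6g} {spacing:.6g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, data in scalars.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, data.ravel(order="F")[:, None], fmt="%.6g")
        for name, data in vectors.items():
            fh.write(f"VECTORS {name} float\n")
            flat = data.reshape(-1, 3, order="F") if data.ndim == 4 else data
            flat = np.stack(
                [data[..., c].ravel(order="F") for c in range(3)], axis=1
            )
            np.savetxt(fh, flat, fmt="%.6g")
    return path


def write_vtk_points(path: str | Path, points: np.ndarray,
                     scalars: dict[str, np.ndarray] | None = None) -> Path:
    """Legacy-VTK POLYDATA vertex cloud (e.g. tracer particles)."""
    scalars = scalars or {}
    n = len(points)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\ngastroflow points\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        np.savetxt(fh, points, fmt="%.6g")
        fh.write(f"VERTICES {n} {2 * n}\n")
        np.savetxt(fh, np.column_stack([np.ones(n, int), np.arange(n)]), fmt="%d")
        if scalars:
            fh.write(f"POINT_DATA {n}\n")
            for name, data in scalars.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(data, float)[:, None], fmt="%.6g")
    return path


def write_vtk_surface(path: str | Path, verts: np.ndarray, faces: np.ndarray) -> Path:
    """Legacy-VTK POLYDATA triangle mesh (geometry surface export)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\ngastroflow surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} float\n")
        np.savetxt(fh, verts, fmt="%.6g")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(faces), 3), faces]), fmt="%d")
    return path


def save_checkpoint(path: str | Path, core) -> Path:
    """HDF5 checkpoint of the full solver state."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for name in ("f", "flags", "mass", "rho", "ux", "uy", "uz", "psi"):
            h5.create_dataset(name, data=getattr(core, name), compression="gzip")
        h5.attrs["t"] = core.t
        h5.attrs["step_count"] = core.step_count
        h5.attrs["emptied_volume"] = core.emptied_volume
        h5.attrs["reservoir"] = core.reservoir
    return path


def load_checkpoint(path: str | Path, core) -> None:
    """Restore solver state in place from an HDF5 checkpoint."""
    with h5py.File(Path(path), "r") as h5:
        for name in ("f", "flags", "mass", "rho", "ux", "uy", "uz", "psi"):
            getattr(core, name)[...] = h5[name][...]
        core.t = float(h5.attrs["t"])
        core.step_count = int(h5.attrs["step_count"])
        core.emptied_volume = float(h5.attrs["emptied_volume"])
        core.reservoir = float(h5.attrs["reservoir"])


def dump_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
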