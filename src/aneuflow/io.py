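"""Plain-text point-cloud serialization: legacy VTK polydata and ASCII PLY.

Only the small subset of each format needed for hemodynamic point clouds is
implemented: point coordinates plus optional per-point ``velocity`` (vector),
``pressure`` (scalar) and ``region`` (integer label) arrays.  Files written
here load in standard VTK viewers; the reader also accepts legacy-VTK
UNSTRUCTURED_GRID files so externally computed CFD fields can be imported.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np

__all__ = ["write_vtk_cloud", "read_vtk_cloud", "write_ply_cloud", "read_ply_cloud"]

_FMT = "%.9g"


def _rows(arr: np.ndarray) -> str:
    return "\n".join(" ".join(_FMT % v for v in row) for row in np.atleast_2d(arr))


def write_vtk_cloud(path, points: np.ndarray,
                    velocity: Optional[np.ndarray] = None,
                    pressure: Optional[np.ndarray] = None,
                    region: Optional[np.ndarray] = None) -> None:
    """Write a point cloud as legacy-VTK ASCII POLYDATA with vertex cells."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    lines = [
        "# vtk DataFile Version 3.0",
        "aneuflow point cloud",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
        _rows(points),
        f"VERTICES {n} {2 * n}",
        "\n".join(f"1 {i}" for i in range(n)),
    ]
    data_lines = []
    if velocity is not None:
        velocity = np.asarray(velocity, dtype=float).reshape(n, 3)
        data_lines += ["VECTORS velocity float", _rows(velocity)]
    if pressure is not None:
        pressure = np.asarray(pressure, dtype=float).reshape(n)
        data_lines += ["SCALARS pressure float 1", "LOOKUP_TABLE default",
                       "\n".join(_FMT % v for v in pressure)]
    if region is not None:
        region = np.asarray(region, dtype=int).reshape(n)
        data_lines += ["SCALARS region int 1", "LOOKUP_TABLE default",
                       "\n".join(str(v) for v in region)]
    if data_lines:
        lines += [f"POINT_DATA {n}"] + data_lines
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_cloud(path) -> Dict[str, np.ndarray]:
    """Read the subset of legacy-VTK ASCII written by :func:`write_vtk_cloud`.

    Also accepts UNSTRUCTURED_GRID data sets and arbitrary extra arrays are
    ignored.  Returns a dict with ``points`` and any of ``velocity``,
    ``pressure``, ``region`` present in the file.
    """
    tokens = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# vtk"):
            raise ValueError(f"{path}: not a legacy VTK file")
        fh.readline()  # title
        fmt = fh.readline().strip().upper()
        if fmt != "ASCII":
            raise ValueError(f"{path}: only ASCII legacy VTK is supported")
        dataset = fh.readline().split()
        if len(dataset) != 2 or dataset[1] not in ("POLYDATA", "UNSTRUCTURED_GRID"):
            raise ValueError(f"{path}: unsupported dataset type {dataset!r}")
        for line in fh:
            tokens.extend(line.split())

    out: Dict[str, np.ndarray] = {}
    i = 0
    n_points = 0
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok == "POINTS":
            n_points = int(tokens[i + 1])
            vals = np.array(tokens[i + 3:i + 3 + 3 * n_points], dtype=float)
            out["points"] = vals.reshape(n_points, 3)
            i += 3 + 3 * n_points
        elif tok in ("VERTICES", "CELLS", "POLYGONS", "LINES"):
            n_items = int(tokens[i + 1])
            n_vals = int(tokens[i + 2])
            i += 3 + n_vals
            if i < len(tokens) and tokens[i].upper() == "OFFSETS":  # XML-era layout
                i += 2 + n_items
        elif tok == "CELL_TYPES":
            n_items = int(tokens[i + 1])
            i += 2 + n_items
        elif tok in ("POINT_DATA", "CELL_DATA"):
            i += 2
        elif tok == "VECTORS":
            name = tokens[i + 1]
            vals = np.array(tokens[i + 3:i + 3 + 3 * n_points], dtype=float)
            out[name] = vals.reshape(n_points, 3)
            i += 3 + 3 * n_points
        elif tok == "SCALARS":
            name = tokens[i + 1]
            dtype = float if tokens[i + 2].lower() in ("float", "double") else int
            try:  # optional n_components token
                int(tokens[i + 3])
                j = i + 4
            except ValueError:
                j = i + 3
            if tokens[j].upper() == "LOOKUP_TABLE":
                j += 2
            vals = np.array(tokens[j:j + n_points], dtype=dtype)
            out[name] = vals
            i = j + n_points
        else:
            i += 1
    if "points" not in out:
        raise ValueError(f"{path}: no POINTS block found")
    return out


def write_ply_cloud(path, points: np.ndarray,
                    velocity: Optional[np.ndarray] = None,
                    pressure: Optional[np.ndarray] = None,
                    region: Optional[np.ndarray] = None) -> None:
    """Write a point cloud as ASCII PLY with optional per-vertex properties."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    header = ["ply", "format ascii 1.0", f"element vertex {n}",
              "property double x", "property double y", "property double z"]
    cols = [points]
    if velocity is not None:
        header += ["property double vx", "property double vy", "property double vz"]
        cols.append(np.asarray(velocity, dtype=float).reshape(n, 3))
    if pressure is not None:
        header += ["property double pressure"]
        cols.append(np.asarray(pressure, dtype=float).reshape(n, 1))
    if region is not None:
        header += ["property int region"]
        cols.append(np.asarray(region, dtype=float).reshape(n, 1))
    header += ["end_header"]
    body = np.concatenate(cols, axis=1)
    Path(path).write_text("\n".join(header) + "\n" + _rows(body) + "\n")


def read_ply_cloud(path) -> Dict[str, np.ndarray]:
    """Read ASCII PLY written by :func:`write_ply_cloud`."""
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"{path}: not a PLY file")
        props = []
        n = 0
        for line in fh:
            parts = line.split()
            if parts[0] == "element" and parts[1] == "vertex":
                n = int(parts[2])
            elif parts[0] == "property":
                props.append(parts[2])
            elif parts[0] == "end_header":
                break
        body = np.loadtxt(fh, ndmin=2)
    if body.shape != (n, len(props)):
        raise ValueError(f"{path}: body shape {body.shape} != ({n}, {len(props)})")
    cols = {p: body[:, i] for i, p in enumerate(props)}
    out: Dict[str, np.ndarray] = {"points": np.stack([cols["x"], cols["y"], cols["z"]], axis=1)}
    if "vx" in cols:
        out["velocity"] = np.stack([cols["vx"], cols["vy"], cols["vz"]], axis=1)
    if "pressure" in cols:
        out["pressure"] = cols["pressure"]
    if "region" in cols:
        out["region"] = cols["region"].astype(int)
    return out
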