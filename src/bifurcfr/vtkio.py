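"""Minimal legacy-VTK (ASCII) I/O for flow fields and centerlines.

Supports the subset of the legacy format the package needs: unstructured
grids of tetrahedra with point-data arrays ``velocity`` (m/s) and
``pressure`` (mmHg or Pa with a declared unit), and polyline polydata for
centerlines.  XML formats (.vtu/.vtp) are not handled.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError
from .fields import FlowField
from .geometry import Centerline
from .hemodynamics import MMHG_PER_PA


def write_flow_field(path: str, field: FlowField) -> None:
    """Write a FlowField as a legacy-VTK ASCII unstructured grid."""
    n = field.n_points
    m = len(field.cells)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbifurcfr flow field\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} float\n")
        np.savetxt(fh, field.points, fmt="%.6g")
        fh.write(f"CELLS {m} {5 * m}\n")
        np.savetxt(fh, np.column_stack([np.full(m, 4), field.cells]), fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10), fmt="%d")  # VTK_TETRA
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS pressure_mmHg float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, field.pressure, fmt="%.6g")
        fh.write("VECTORS velocity float\n")
        np.savetxt(fh, field.velocity, fmt="%.6g")


def write_point_scalar(path_in: str, name: str, values: np.ndarray) -> None:
    """Append one more point-data scalar array (e.g. LNH) to a written file."""
    with open(path_in, "a") as fh:
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, np.asarray(values), fmt="%.6g")


def read_flow_field(path: str, pressure_unit: str = "mmHg") -> FlowField:
    """Read a legacy-VTK ASCII tetrahedral grid with velocity and pressure
    point data.  ``pressure_unit`` is 'mmHg' or 'Pa'."""
    if pressure_unit not in ("mmHg", "Pa"):
        raise InvalidParameterError("pressure_unit must be 'mmHg' or 'Pa'")
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))

    def find(word: str, start: int = 0) -> int:
        for k in range(start, len(tokens)):
            if tokens[k].upper() == word:
                return k
        raise InvalidParameterError(f"token {word!r} not found in {path}")

    k = find("POINTS")
    n = int(tokens[k + 1])
    pts = np.array(tokens[k + 3:k + 3 + 3 * n], dtype=float).reshape(n, 3)

    k = find("CELLS")
    m = int(tokens[k + 1])
    raw = np.array(tokens[k + 3:k + 3 + 5 * m], dtype=int).reshape(m, 5)
    if np.any(raw[:, 0] != 4):
        raise InvalidParameterError("only tetrahedral cells are supported")
    cells = raw[:, 1:]

    def read_scalar(name_candidates):
        for cand in name_candidates:
            for k in range(len(tokens)):
                if tokens[k] == "SCALARS" and tokens[k + 1].lower().startswith(cand):
                    start = k + 6  # SCALARS name type 1 LOOKUP_TABLE default
                    return np.array(tokens[start:start + n], dtype=float)
        raise InvalidParameterError(f"no scalar array {name_candidates} in {path}")

    pressure = read_scalar(["pressure"])
    if pressure_unit == "Pa":
        pressure = pressure * MMHG_PER_PA
    k = find("VECTORS")
    vel = np.array(tokens[k + 3:k + 3 + 3 * n], dtype=float).reshape(n, 3)

    a = pts[cells[:, 0]]
    vols = np.abs(np.einsum("ij,ij->i", pts[cells[:, 1]] - a,
                            np.cross(pts[cells[:, 2]] - a, pts[cells[:, 3]] - a))) / 6.0
    return FlowField(points=pts, velocity=vel, pressure=pressure,
                     cells=cells, cell_volumes=vols)


def write_centerline(path: str, cl: Centerline) -> None:
    """Write a centerline as legacy-VTK polyline polydata with diameter and
    arc-length point data."""
    n = len(cl)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbifurcfr centerline\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        np.savetxt(fh, cl.positions, fmt="%.6g")
        fh.write(f"LINES 1 {n + 1}\n")
        fh.write(" ".join([str(n)] + [str(i) for i in range(n)]) + "\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS diameter_mm float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, cl.diameters, fmt="%.6g")
        fh.write("SCALARS arc_length_mm float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, cl.arc_length, fmt="%.6g")
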