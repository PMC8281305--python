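"""Minimal VTK legacy (ASCII) unstructured-grid writer/reader.

Covers exactly what the package needs: tetrahedral meshes with named scalar
point-data arrays (ventricular coordinates, segment labels, surface labels,
activation times).  Surface labels are encoded as integers
(0 interior, 1 endo, 2 epi, 3 base) in the ``surface_label`` array.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

__all__ = ["write_vtk", "read_vtk", "SURFACE_CODES"]

SURFACE_CODES = {"": 0, "endo": 1, "epi": 2, "base": 3}
_CODES_SURFACE = {v: k for k, v in SURFACE_CODES.items()}

VTK_TETRA = 10


def write_vtk(
    path,
    points: np.ndarray,
    tets: np.ndarray,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    title: str = "pvcloc mesh",
) -> None:
    points = np.asarray(points, dtype=float)
    tets = np.asarray(tets, dtype=int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(title[:255] + "\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(points)} double\n")
        np.savetxt(f, points, fmt="%.10g")
        f.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        np.savetxt(f, np.column_stack([np.full(len(tets), 4), tets]), fmt="%d")
        f.write(f"CELL_TYPES {len(tets)}\n")
        np.savetxt(f, np.full(len(tets), VTK_TETRA), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {len(points)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.shape != (len(points),):
                    raise ValueError(f"point-data array {name!r} has wrong shape")
                if np.issubdtype(arr.dtype, np.integer):
                    f.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%d")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.10g")


def read_vtk(path) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray]]:
    """Read back a file written by :func:`write_vtk`.

    Returns (points, tets, point_data)."""
    with open(path) as f:
        tokens = f.read().split()
    i = 0

    def expect(word):
        nonlocal i
        while tokens[i].upper() != word:
            i += 1
        i += 1

    expect("POINTS")
    n_pts = int(tokens[i]); i += 2  # skip dtype
    points = np.array(tokens[i : i + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i += 3 * n_pts
    expect("CELLS")
    n_cells = int(tokens[i]); total = int(tokens[i + 1]); i += 2
    raw = np.array(tokens[i : i + total], dtype=int)
    i += total
    tets = raw.reshape(n_cells, 5)[:, 1:]
    expect("CELL_TYPES")
    i += n_cells + 1  # count token consumed by expect? no: expect consumed keyword; skip count+values
    # re-sync: after CELL_TYPES the next token is the count then the values
    # (handled above by skipping n_cells + 1 tokens)
    point_data: Dict[str, np.ndarray] = {}
    while i < len(tokens):
        if tokens[i].upper() == "POINT_DATA":
            i += 2
        elif tokens[i].upper() == "SCALARS":
            name, dtype = tokens[i + 1], tokens[i + 2]
            i += 4  # SCALARS name type ncomp
            if tokens[i].upper() == "LOOKUP_TABLE":
                i += 2
            vals = np.array(
                tokens[i : i + n_pts], dtype=int if dtype == "int" else float
            )
            i += n_pts
            point_data[name] = vals
        else:
            i += 1
    return points, tets, point_data
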