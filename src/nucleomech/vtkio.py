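"""Minimal legacy-VTK (ASCII, unstructured grid) export for inspection.

Writes meshes with optional point/cell data so results can be opened in
ParaView.  Only export is supported; the package never needs to read VTK.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_VTK_TET = 10
_VTK_TRI = 5
_VTK_LINE = 3


def write_vtk(
    path: str | Path,
    points: np.ndarray,
    cells: list[tuple[int, np.ndarray]],
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "nucleomech export",
) -> Path:
    """Write an unstructured grid.

    Parameters
    ----------
    cells
        List of (vtk_cell_type, connectivity array) blocks, e.g.
        ``[(10, tets), (5, tris)]``.
    point_data, cell_data
        Scalar (n,) or vector (n, 3) float arrays keyed by field name.
    """
    path = Path(path)
    points = np.asarray(points, dtype=float)
    with path.open("w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt="%.10g")
        n_cells = sum(len(c) for _, c in cells)
        size = sum(len(c) * (c.shape[1] + 1) for _, c in cells)
        fh.write(f"CELLS {n_cells} {size}\n")
        for _, conn in cells:
            block = np.column_stack([np.full(len(conn), conn.shape[1]), conn])
            np.savetxt(fh, block, fmt="%d")
        fh.write(f"CELL_TYPES {n_cells}\n")
        for ctype, conn in cells:
            np.savetxt(fh, np.full(len(conn), ctype), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {len(points)}\n")
            _write_fields(fh, point_data)
        if cell_data:
            fh.write(f"CELL_DATA {n_cells}\n")
            _write_fields(fh, cell_data)
    return path


def _write_fields(fh, fields: dict[str, np.ndarray]) -> None:
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.10g")
        else:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(-1, 1), fmt="%.10g")


def write_mesh_vtk(path, mesh, point_data=None) -> Path:
    """Export a :class:`~nucleomech.geometry.Mesh` with part labels."""
    cells = [(_VTK_TET, mesh.tets), (_VTK_TRI, mesh.shell_tris)]
    cell_data = {
        "part": np.concatenate([mesh.tet_part.astype(float), np.full(len(mesh.shell_tris), 2.0)])
    }
    return write_vtk(path, mesh.nodes, cells, point_data=point_data, cell_data=cell_data)
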