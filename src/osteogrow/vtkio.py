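"""Minimal ASCII legacy-VTK writer for geometry and field snapshots."""

from __future__ import annotations

import numpy as np

from .porous_geometry import FEMesh

__all__ = ["write_vtk"]


def write_vtk(path, mesh: FEMesh, cell_data: dict | None = None,
              point_data: dict | None = None, title: str = "osteogrow") -> None:
    """Write an unstructured-grid legacy VTK file (triangles, z = 0)."""
    cell_data = cell_data or {}
    point_data = point_data or {}
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        f.write(f"CELLS {mesh.n_elems} {4 * mesh.n_elems}\n")
        for tri in mesh.elems:
            f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        f.write(f"CELL_TYPES {mesh.n_elems}\n")
        f.write("5\n" * mesh.n_elems)
        if cell_data:
            f.write(f"CELL_DATA {mesh.n_elems}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr.astype(float), fmt="%.9g")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2:
                    f.write(f"VECTORS {name} double\n")
                    for row in arr:
                        z = row[2] if len(row) > 2 else 0.0
                        f.write(f"{row[0]:.9g} {row[1]:.9g} {z:.9g}\n")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr.astype(float), fmt="%.9g")
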