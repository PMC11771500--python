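"""Legacy-ASCII VTK export of cross-section meshes and solution fields.

Writes unstructured grids of 4-node quadrilaterals (VTK cell type 9) with
optional point and cell data, readable by ParaView and compatible tools.
Output is plain text and deterministic for fixed inputs.
"""

from __future__ import annotations

import numpy as np

from .geometry import Mesh

__all__ = ["write_vtk"]


def _fmt(x: float) -> str:
    return f"{x:.9g}"


def write_vtk(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None, displacements=None) -> None:
    """Write the mesh (optionally deformed by ``displacements``) to ``path``.

    ``point_data``/``cell_data`` map field names to scalar arrays of length
    n_nodes / n_elems, or (n, k) arrays written as k-component fields.
    """

    coords = mesh.nodes if displacements is None else mesh.nodes + displacements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("aussim cross-section\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in coords:
            fh.write(f"{_fmt(x)} {_fmt(y)} 0\n")
        m = mesh.n_elems
        fh.write(f"CELLS {m} {5 * m}\n")
        for quad in mesh.elems:
            fh.write("4 " + " ".join(str(int(i)) for i in quad) + "\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["9"] * m) + "\n")

        def _write_block(data: dict, n: int) -> None:
            for name, arr in data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(_fmt(v) for v in arr) + "\n")
                else:
                    k = arr.shape[1]
                    fh.write(f"FIELD {name}_field 1\n{name} {k} {n} double\n")
                    for row in arr:
                        fh.write(" ".join(_fmt(v) for v in row) + "\n")

        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            _write_block(point_data, mesh.n_nodes)
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            _write_block(cell_data, m)
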