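"""Legacy-ASCII VTK export of hexahedral meshes with point/cell data.

A minimal writer for the classic unstructured-grid format (readable by
ParaView and friends): hexahedral cells plus named scalar/vector arrays
at points or cells.  ASCII keeps result files inspectable and diffable.
"""

from __future__ import annotations

import numpy as np

from .mesh import Mesh

__all__ = ["write_vtk"]

_VTK_HEXAHEDRON = 12


def _write_array(f, name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        for v in arr:
            f.write(f"{v:.9g}\n")
    elif arr.ndim == 2 and arr.shape[1] == 3:
        f.write(f"VECTORS {name} double\n")
        for v in arr:
            f.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    else:
        raise ValueError(f"array {name!r} must be (n,) or (n, 3)")


def write_vtk(
    path,
    mesh: Mesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "cartmech output",
) -> None:
    """Write the mesh and optional data arrays as a legacy VTK file."""
    with open(path, "w") as f:
        f.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x in mesh.nodes:
            f.write(f"{x[0]:.9g} {x[1]:.9g} {x[2]:.9g}\n")
        E = mesh.n_elements
        f.write(f"CELLS {E} {9 * E}\n")
        for el in mesh.hex_elements:
            f.write("8 " + " ".join(str(int(i)) for i in el) + "\n")
        f.write(f"CELL_TYPES {E}\n")
        f.write("\n".join([str(_VTK_HEXAHEDRON)] * E) + "\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                _write_array(f, name, arr)
        cell = dict(cell_data or {})
        cell.setdefault("layer_id", mesh.layer_id.astype(float))
        f.write(f"CELL_DATA {E}\n")
        for name, arr in cell.items():
            _write_array(f, name, arr)


def write_history_series(path_prefix, history, cell_data_fn=None) -> list:
    """Write one VTK file per solution step: displacements, pore pressure,
    and optional per-element arrays from ``cell_data_fn(record)``.

    Returns the list of written paths (``<prefix>_NNN.vtk``).
    """
    paths = []
    for i, rec in enumerate(history.records):
        cell = dict(cell_data_fn(rec)) if cell_data_fn else {}
        path = f"{path_prefix}_{i:03d}.vtk"
        write_vtk(path, history.mesh,
                  point_data={"displacement": rec.u, "pore_pressure": rec.p},
                  cell_data=cell, title=f"step {i} t={rec.time:.6g}s")
        paths.append(path)
    return paths
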