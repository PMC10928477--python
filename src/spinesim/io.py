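"""Export helpers: legacy-VTK writers and array containers.

Meshes go to PLY/OFF through trimesh (see ``SpineMesh.save``); time-stamped
mesh series and lattice fields can additionally be written as ASCII legacy
VTK for visualization, and lattice fields as ``.npz`` containers carrying
the grid metadata (origin, spacing, shape).
"""

from __future__ import annotations

import numpy as np

from .distance_field import LatticeGrid
from .geometry import SpineMesh

__all__ = ["write_vtk_polydata", "write_vtk_image", "save_fields", "load_fields"]


def write_vtk_polydata(path: str, mesh: SpineMesh, comment: str = "spine") -> None:
    """Triangle mesh as ASCII legacy VTK polydata (coordinates in um)."""
    V, F = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{comment}\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(V)} double\n")
        np.savetxt(fh, V, fmt="%.9g")
        fh.write(f"POLYGONS {len(F)} {4 * len(F)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(F), 3), F]), fmt="%d")


def write_vtk_image(
    path: str, grid: LatticeGrid, fields: dict, comment: str = "fields"
) -> None:
    """Scalar lattice fields as ASCII legacy VTK structured points."""
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{comment}\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}\n")
        fh.write(f"SPACING {grid.spacing} {grid.spacing} {grid.spacing}\n")
        fh.write(f"POINT_DATA {grid.n_points}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK expects x varying fastest; our flat order has z fastest
            vals = grid.reshape(np.asarray(arr)).transpose(2, 1, 0).ravel()
            np.savetxt(fh, vals, fmt="%.9g")


def save_fields(path: str, grid: LatticeGrid, **arrays) -> None:
    """Portable array container with grid metadata."""
    np.savez_compressed(
        path,
        origin=np.asarray(grid.origin),
        spacing=np.asarray(grid.spacing),
        shape=np.asarray(grid.shape),
        **arrays,
    )


def load_fields(path: str):
    data = np.load(path)
    grid = LatticeGrid(
        tuple(data["origin"]), float(data["spacing"]), tuple(data["shape"])
    )
    arrays = {
        k: data[k] for k in data.files
        if k not in ("origin", "spacing", "shape")
    }
    return grid, arrays
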