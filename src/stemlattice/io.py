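"""Plain-text exporters: legacy-ASCII VTK for 2D fields, ASCII STL for
lattice surfaces, CSV for design tables.  Kept deliberately minimal — these
write the subset of each format the pipeline produces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DesignVariables, QuadMesh

__all__ = ["write_vtk_quad", "write_vtk_tri", "write_stl_ascii",
           "designs_to_csv", "designs_from_csv"]


def _vtk_header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")


def _write_data(fh, kind: str, n: int, data: dict[str, np.ndarray]) -> None:
    if not data:
        return
    fh.write(f"{kind} {n}\n")
    for name, values in data.items():
        values = np.asarray(values)
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, values.reshape(-1, 1), fmt="%.9g")


def write_vtk_quad(path, mesh: QuadMesh, point_data: dict | None = None,
                   cell_data: dict | None = None) -> None:
    """Write a quad mesh with optional nodal/element scalar fields.

    Per-integration-point fields must be reduced to per-element (e.g. a
    4-point mean) before export; VTK legacy has no integration-point slot.
    """
    path = Path(path)
    with path.open("w") as fh:
        _vtk_header(fh, "stemlattice quad mesh")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(fh, np.column_stack([mesh.nodes, np.zeros(mesh.n_nodes)]),
                   fmt="%.9g")
        fh.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(mesh.n_elements, 4), mesh.elements]), fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(fh, np.full((mesh.n_elements, 1), 9), fmt="%d")
        _write_data(fh, "POINT_DATA", mesh.n_nodes, point_data or {})
        cells = dict(cell_data or {})
        cells.setdefault("region", mesh.region.astype(float))
        _write_data(fh, "CELL_DATA", mesh.n_elements, cells)


def write_vtk_tri(path, vertices: np.ndarray, faces: np.ndarray,
                  point_data: dict | None = None) -> None:
    """Write a 3D triangle surface mesh."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    with Path(path).open("w") as fh:
        _vtk_header(fh, "stemlattice lattice surface")
        fh.write(f"POINTS {len(vertices)} float\n")
        np.savetxt(fh, vertices, fmt="%.9g")
        fh.write(f"CELLS {len(faces)} {4 * len(faces)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(faces), 3), faces]), fmt="%d")
        fh.write(f"CELL_TYPES {len(faces)}\n")
        np.savetxt(fh, np.full((len(faces), 1), 5), fmt="%d")
        _write_data(fh, "POINT_DATA", len(vertices), point_data or {})


def write_stl_ascii(path, vertices: np.ndarray, faces: np.ndarray,
                    name: str = "stemlattice") -> None:
    """Write an ASCII STL surface (facet normals from right-hand winding)."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    tri = vertices[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    with Path(path).open("w") as fh:
        fh.write(f"solid {name}\n")
        for (nx, ny, nz), t in zip(n, tri):
            fh.write(f" facet normal {nx:.9g} {ny:.9g} {nz:.9g}\n  outer loop\n")
            for vx, vy, vz in t:
                fh.write(f"   vertex {vx:.9g} {vy:.9g} {vz:.9g}\n")
            fh.write("  endloop\n endfacet\n")
        fh.write(f"endsolid {name}\n")


def designs_to_csv(path, designs: list[DesignVariables]) -> None:
    pd.DataFrame([{k: getattr(d, k) for k in DesignVariables.names()}
                  for d in designs]).to_csv(path, index=False)


def designs_from_csv(path) -> list[DesignVariables]:
    frame = pd.read_csv(path)
    return [DesignVariables(**{k: float(row[k]) for k in DesignVariables.names()})
            for _, row in frame.iterrows()]
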