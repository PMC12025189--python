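"""Shared fixtures: small meshes and a midrange implant design."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from stemlattice.geometry import DesignVariables, LoadCase, QuadMesh, Region, \
    build_conventional, implant_load_case


def make_grid_mesh(Lx: float, Ly: float, nx: int, ny: int,
                   region: Region = Region.REMODEL,
                   distort: float = 0.0, seed: int = 0) -> QuadMesh:
    """Structured rectangle mesh; optional random interior-node distortion."""
    xs = np.linspace(0, Lx, nx + 1)
    ys = np.linspace(0, Ly, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    if distort:
        rng = np.random.default_rng(seed)
        interior = ((nodes[:, 0] > 1e-9) & (nodes[:, 0] < Lx - 1e-9)
                    & (nodes[:, 1] > 1e-9) & (nodes[:, 1] < Ly - 1e-9))
        nodes[interior] += rng.uniform(-distort, distort, size=(interior.sum(), 2))
    nid = lambda i, j: j * (nx + 1) + i
    elems = [[nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
             for j in range(ny) for i in range(nx)]
    return QuadMesh(nodes=nodes, elements=np.array(elems),
                    region=np.full(len(elems), int(region)),
                    outline=box(0, 0, Lx, Ly))


def cantilever_case(mesh: QuadMesh, P: float = 1.0) -> LoadCase:
    Lx = mesh.nodes[:, 0].max()
    Ly = mesh.nodes[:, 1].max()
    fixed = np.flatnonzero(mesh.nodes[:, 0] < 1e-9)
    tip = mesh.nearest_node(Lx, Ly / 2)
    return LoadCase(fixed_nodes=fixed, load_node=tip, value=(0.0, -P))


@pytest.fixture(scope="session")
def midrange_dv() -> DesignVariables:
    return DesignVariables.midrange()


@pytest.fixture(scope="session")
def midrange_mesh(midrange_dv):
    mesh = build_conventional(midrange_dv, elem_size=2.5)
    assert mesh is not None
    return mesh


@pytest.fixture(scope="session")
def midrange_load(midrange_mesh):
    return implant_load_case(midrange_mesh)
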