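"""Shared fixtures: a coarse LV mesh (fast), its coordinates and segment
models, electrodes, and helpers to build tiny ad-hoc meshes."""

from __future__ import annotations

import numpy as np
import pytest

from pvcloc.geometry import (
    ElectrodeParams,
    EPParams,
    GeometryParams,
    VentricularMesh,
    assign_fibers,
    build_lv_mesh,
    build_segment_model,
    compute_uvc,
    place_electrodes,
)

COARSE = GeometryParams(edge_length=5.0)


@pytest.fixture(scope="session")
def geo_params():
    return COARSE


@pytest.fixture(scope="session")
def mesh_uvc(geo_params):
    mesh = build_lv_mesh(geo_params)
    uvc = compute_uvc(mesh)
    mesh = assign_fibers(mesh, uvc)
    return mesh, uvc


@pytest.fixture(scope="session")
def mesh(mesh_uvc):
    return mesh_uvc[0]


@pytest.fixture(scope="session")
def uvc(mesh_uvc):
    return mesh_uvc[1]


@pytest.fixture(scope="session")
def seg17(mesh_uvc):
    return build_segment_model(*mesh_uvc, mode=17)


@pytest.fixture(scope="session")
def seg68(mesh_uvc):
    return build_segment_model(*mesh_uvc, mode=68)


@pytest.fixture(scope="session")
def electrodes(geo_params):
    return place_electrodes(ElectrodeParams(), geo_params)


@pytest.fixture(scope="session")
def ep():
    return EPParams()


# ---------------------------------------------------------------------------
# tiny ad-hoc meshes
# ---------------------------------------------------------------------------

_HEX_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 7, 5],
        [0, 5, 7, 4],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
    ]
)


def make_rod_mesh(n_cells: int, dx: float, cross: float = 5.0) -> VentricularMesh:
    """A straight rod of hexes (split into tets) along +x.

    ``cross`` is the cross-section size; a tall cross-section keeps diagonal
    graph edges slow so axial propagation follows the straight edge path.
    """
    nx = n_cells + 1
    nodes = []
    for i in range(nx):
        for j in (0, 1):
            for k in (0, 1):
                nodes.append([i * dx, j * cross, k * cross])
    nodes = np.array(nodes, dtype=float)

    def nid(i, j, k):
        return i * 4 + j * 2 + k

    tets = []
    for i in range(n_cells):
        corners = [
            nid(i, 0, 0),
            nid(i, 0, 1),
            nid(i, 1, 0),
            nid(i, 1, 1),
            nid(i + 1, 0, 0),
            nid(i + 1, 0, 1),
            nid(i + 1, 1, 0),
            nid(i + 1, 1, 1),
        ]
        for t in _HEX_TETS:
            tets.append([corners[c] for c in t])
    tets = np.array(tets, dtype=int)
    return VentricularMesh(
        node_coords=nodes,
        elements=tets,
        surface_label=np.array([""] * len(nodes), dtype="U4"),
        apex_point=np.zeros(3),
        base_point=np.array([n_cells * dx, 0.0, 0.0]),
        base_normal=np.array([1.0, 0.0, 0.0]),
        target_edge_length=dx,
    )


def with_fibers(mesh_obj: VentricularMesh, direction) -> VentricularMesh:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    import dataclasses

    return dataclasses.replace(
        mesh_obj, fiber=np.tile(d, (mesh_obj.n_elements, 1))
    )


def make_random_mesh(n_nodes: int, seed: int) -> VentricularMesh:
    """Random Delaunay tetrahedral mesh with random unit fibers."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 20.0, size=(n_nodes, 3))
    tri = Delaunay(pts)
    fibers = rng.standard_normal((len(tri.simplices), 3))
    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
    import dataclasses

    mesh_obj = VentricularMesh(
        node_coords=pts,
        elements=tri.simplices.copy(),
        surface_label=np.array([""] * n_nodes, dtype="U4"),
        apex_point=np.zeros(3),
        base_point=np.array([20.0, 0.0, 0.0]),
        base_normal=np.array([1.0, 0.0, 0.0]),
        target_edge_length=2.0,
        fiber=fibers,
    )
    return mesh_obj
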