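"""Synthetic left-ventricular geometry, ventricular coordinates and electrodes.

The left ventricle is modelled as a truncated-ellipsoid shell: the wall lies
between an endocardial and an epicardial ellipsoid of revolution sharing a
common centre on the long (z) axis, cut by a flat base plane.  The apex sits
at the origin, the base plane at ``z = epi_length`` (mm), so "superior" is
+z.  The azimuthal reference direction (phi = 0, called "septal" throughout)
is +x.

The mesh is built from a structured (transmural x longitudinal x
circumferential) node lattice whose hexahedral / prismatic cells are split
into tetrahedra, which keeps construction deterministic and lets surface
nodes lie exactly on the two ellipsoids and the base plane.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "GeometryParams",
    "EPParams",
    "VentricularMesh",
    "UVCoordinates",
    "SegmentModel",
    "ElectrodeParams",
    "ElectrodeSet",
    "PacingSite",
    "build_lv_mesh",
    "assign_fibers",
    "compute_uvc",
    "build_segment_model",
    "place_electrodes",
    "sample_pacing_sites",
    "wrap_angle",
]

ECG_ELECTRODES = ("V1", "V2", "V3", "V4", "V5", "V6", "RA", "LA", "LL")
CIED_ELECTRODES = (
    "RVtip",
    "RVring",
    "RVcoil",
    "SVC",
    "CAN",
    "LVtip1",
    "LVtip2",
    "LVtip3",
    "LVtip4",
)


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = (-a + np.pi) % (2.0 * np.pi)
    out = np.pi - out
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the truncated-ellipsoid LV (all mm).

    ``epi_length`` is the apex-to-base extent of the epicardium; the long
    semi-axis of the epicardial ellipsoid is ``long_axis_fraction *
    epi_length`` (must lie in (1/2, 1) for a non-degenerate basal opening).
    """

    epi_length: float = 90.0
    epi_radius: float = 30.0
    wall_thickness: float = 10.0
    edge_length: float = 2.5
    long_axis_fraction: float = 11.0 / 18.0  # -> 55 mm semi-axis at default size

    def validate(self) -> None:
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        c_epi = self.long_axis_fraction * self.epi_length
        if not (0.5 * self.epi_length < c_epi < self.epi_length):
            raise ValueError(
                "long_axis_fraction must be in (1/2, 1) for a truncated ellipsoid"
            )
        if self.wall_thickness >= self.epi_radius:
            raise ValueError("endocardial radius would be non-positive (endo >= epi)")
        c_endo = c_epi - self.wall_thickness
        if c_endo <= 0 or self.epi_length - c_epi >= c_endo:
            raise ValueError("endocardial ellipsoid does not reach the base plane")


@dataclass(frozen=True)
class EPParams:
    """Tissue electrophysiology parameters.

    Conduction velocities are in m/s (numerically equal to mm/ms, the unit
    used on the mesh).  The intra/extracellular conductivity pairs along and
    transverse to the fiber are carried as metadata; only ``cv_long``,
    ``cv_trans`` and the two bulk conductivities enter any computation.
    """

    cv_long: float = 0.5455
    cv_trans: float = 0.1802
    bcl_ms: float = 400.0
    sigma_bath: float = 0.2
    sigma_intra: float = 0.1845
    sigma_intra_meta: Tuple[float, float] = (0.1845, 0.0493)
    sigma_extra_meta: Tuple[float, float] = (0.6628, 0.1769)

    def validate(self) -> None:
        if not (self.cv_long > self.cv_trans > 0):
            raise ValueError("require cv_long > cv_trans > 0")
        if self.sigma_bath <= 0 or self.sigma_intra <= 0:
            raise ValueError("conductivities must be positive")


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------


@dataclass
class VentricularMesh:
    """Tetrahedral LV mesh with surface labels and landmarks.

    ``surface_label`` holds one of '', 'endo', 'epi', 'base' per node (''
    for interior nodes; every boundary node carries exactly one label).
    ``param_tsv`` stores the structured construction parameters
    (transmural t, longitudinal s, circumferential v in [0,1]) per node for
    meshes built by :func:`build_lv_mesh`; it is ``None`` for ad-hoc meshes.
    """

    node_coords: np.ndarray  # (n_nodes, 3) mm
    elements: np.ndarray  # (n_elem, 4) int
    surface_label: np.ndarray  # (n_nodes,) unicode
    apex_point: np.ndarray  # (3,)
    base_point: np.ndarray  # (3,)
    base_normal: np.ndarray  # (3,)
    target_edge_length: float
    fiber: Optional[np.ndarray] = None  # (n_elem, 3) unit vectors
    params: Optional[GeometryParams] = None
    param_tsv: Optional[np.ndarray] = None  # (n_nodes, 3)

    # -- derived quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(self.node_coords.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.elements.shape[0])

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.elements].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        x = self.node_coords[self.elements]
        a, b, c = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
        return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0

    def edges(self) -> np.ndarray:
        """Unique undirected node pairs (sorted) over all tetra edges."""
        pairs = []
        for i, j in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)):
            pairs.append(self.elements[:, (i, j)])
        e = np.vstack(pairs)
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_graph(self) -> csr_matrix:
        """Symmetric sparse adjacency weighted by Euclidean edge length."""
        e = self.edges()
        w = np.linalg.norm(self.node_coords[e[:, 0]] - self.node_coords[e[:, 1]], axis=1)
        n = self.n_nodes
        g = coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return g.tocsr()

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(
            np.linalg.norm(
                self.node_coords[e[:, 0]] - self.node_coords[e[:, 1]], axis=1
            ).mean()
        )

    def validate(self) -> None:
        n_comp, _ = connected_components(self.edge_graph(), directed=False)
        if n_comp != 1:
            raise ValueError(f"mesh is not connected ({n_comp} components)")
        if self.fiber is not None:
            norms = np.linalg.norm(self.fiber, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("fiber vectors must have unit norm")


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------


def _ellipsoid_point(a: float, c: float, zc: float, theta, v):
    """Point on an ellipsoid of revolution, theta from base (theta_b) to pi=apex."""
    st, ct = np.sin(theta), np.cos(theta)
    x, y = a * st * np.cos(v), a * st * np.sin(v)
    z = np.broadcast_to(zc + c * ct, x.shape)
    return np.stack([x, y, z], axis=-1)


def build_lv_mesh(params: GeometryParams = GeometryParams()) -> VentricularMesh:
    """Build the truncated-ellipsoid LV shell mesh.

    Deterministic for fixed parameters.  Surface labels: 'endo' on the inner
    ellipsoid, 'epi' on the outer, 'base' on the truncation plane (base wins
    at the rim where the surfaces meet the plane).
    """
    params.validate()
    h = params.edge_length
    L = params.epi_length
    a_ep, c_ep = params.epi_radius, params.long_axis_fraction * L
    a_en, c_en = a_ep - params.wall_thickness, c_ep - params.wall_thickness
    zc = c_ep  # apex of the epicardium at the origin

    th_b_ep = float(np.arccos((L - zc) / c_ep))
    th_b_en = float(np.arccos((L - zc) / c_en))

    n_t = max(2, int(round(params.wall_thickness / h)) + 1)
    # meridian arc length of the epicardium (numerical quadrature)
    tt = np.linspace(th_b_ep, np.pi, 512)
    arc = np.trapezoid(
        np.hypot(a_ep * np.cos(tt), c_ep * np.sin(tt)), tt
    )
    n_s = max(4, int(round(arc / h)) + 1)
    n_v = max(8, int(round(2.0 * np.pi * a_ep / h)))

    if n_t * ((n_s - 1) * n_v + 1) < 1000:
        raise ValueError(
            "resolution too coarse: fewer than 1000 nodes; decrease edge_length"
        )

    s = np.linspace(0.0, 1.0, n_s)  # 0 = base ring, 1 = apex
    v = 2.0 * np.pi * np.arange(n_v) / n_v
    t = np.linspace(0.0, 1.0, n_t)  # 0 = endo, 1 = epi

    th_en = th_b_en + s * (np.pi - th_b_en)
    th_ep = th_b_ep + s * (np.pi - th_b_ep)

    # ring nodes: s rows 0..n_s-2 are full rings, s = n_s-1 collapses to the axis
    TH_en = th_en[:-1][:, None]
    TH_ep = th_ep[:-1][:, None]
    V = v[None, :]
    P_en = _ellipsoid_point(a_en, c_en, zc, TH_en, V)  # (n_s-1, n_v, 3)
    P_ep = _ellipsoid_point(a_ep, c_ep, zc, TH_ep, V)

    coords: List[np.ndarray] = []
    tsv: List[np.ndarray] = []
    labels: List[str] = []

    def ring_index(it: int, js: int, kv: int) -> int:
        return (it * (n_s - 1) + js) * n_v + kv

    for it, tv in enumerate(t):
        layer = (1.0 - tv) * P_en + tv * P_ep  # (n_s-1, n_v, 3)
        coords.append(layer.reshape(-1, 3))
        grid_s, grid_v = np.meshgrid(s[:-1], v / (2 * np.pi), indexing="ij")
        tsv.append(
            np.column_stack(
                [np.full(grid_s.size, tv), grid_s.ravel(), grid_v.ravel()]
            )
        )
        for js in range(n_s - 1):
            if js == 0:
                lab = "base"
            elif it == 0:
                lab = "endo"
            elif it == n_t - 1:
                lab = "epi"
            else:
                lab = ""
            labels.extend([lab] * n_v)

    # apex axis nodes, one per layer
    apex_base = n_t * (n_s - 1) * n_v
    apex_en = np.array([0.0, 0.0, zc - c_en])
    apex_ep = np.array([0.0, 0.0, 0.0])
    for it, tv in enumerate(t):
        coords.append(((1.0 - tv) * apex_en + tv * apex_ep)[None, :])
        tsv.append(np.array([[tv, 1.0, 0.0]]))
        labels.append("endo" if it == 0 else ("epi" if it == n_t - 1 else ""))

    node_coords = np.vstack(coords)
    param_tsv = np.vstack(tsv)
    surface_label = np.array(labels, dtype="U4")

    # --- connectivity: hexes between full rings, prisms to the apex --------
    tets: List[np.ndarray] = []
    HEX_TETS = np.array(
        [
            [0, 1, 3, 7],
            [0, 1, 7, 5],
            [0, 5, 7, 4],
            [0, 3, 2, 7],
            [0, 2, 6, 7],
            [0, 6, 4, 7],
        ]
    )
    it_idx, js_idx, kv_idx = np.meshgrid(
        np.arange(n_t - 1), np.arange(n_s - 2), np.arange(n_v), indexing="ij"
    )
    it_idx, js_idx, kv_idx = it_idx.ravel(), js_idx.ravel(), kv_idx.ravel()
    kv1 = (kv_idx + 1) % n_v
    corners = np.stack(
        [
            ring_index_arr(it_idx, js_idx, kv_idx, n_s, n_v),
            ring_index_arr(it_idx, js_idx, kv1, n_s, n_v),
            ring_index_arr(it_idx, js_idx + 1, kv_idx, n_s, n_v),
            ring_index_arr(it_idx, js_idx + 1, kv1, n_s, n_v),
            ring_index_arr(it_idx + 1, js_idx, kv_idx, n_s, n_v),
            ring_index_arr(it_idx + 1, js_idx, kv1, n_s, n_v),
            ring_index_arr(it_idx + 1, js_idx + 1, kv_idx, n_s, n_v),
            ring_index_arr(it_idx + 1, js_idx + 1, kv1, n_s, n_v),
        ],
        axis=1,
    )  # (n_hex, 8)
    tets.append(corners[:, HEX_TETS].reshape(-1, 4))

    # prisms between the last full ring (js = n_s-2) and the apex axis
    PRISM_TETS = np.array([[0, 1, 2, 3], [1, 2, 3, 4], [2, 3, 4, 5]])
    it_idx, kv_idx = np.meshgrid(np.arange(n_t - 1), np.arange(n_v), indexing="ij")
    it_idx, kv_idx = it_idx.ravel(), kv_idx.ravel()
    kv1 = (kv_idx + 1) % n_v
    prism = np.stack(
        [
            ring_index_arr(it_idx, np.full_like(it_idx, n_s - 2), kv_idx, n_s, n_v),
            ring_index_arr(it_idx, np.full_like(it_idx, n_s - 2), kv1, n_s, n_v),
            apex_base + it_idx,
            ring_index_arr(it_idx + 1, np.full_like(it_idx, n_s - 2), kv_idx, n_s, n_v),
            ring_index_arr(it_idx + 1, np.full_like(it_idx, n_s - 2), kv1, n_s, n_v),
            apex_base + it_idx + 1,
        ],
        axis=1,
    )  # (n_prism, 6)
    tets.append(prism[:, PRISM_TETS].reshape(-1, 4))

    elements = np.vstack(tets)
    # drop degenerate (zero-volume) tets if any slip through
    mesh = VentricularMesh(
        node_coords=node_coords,
        elements=elements,
        surface_label=surface_label,
        apex_point=apex_ep,
        base_point=np.array([0.0, 0.0, L]),
        base_normal=np.array([0.0, 0.0, 1.0]),
        target_edge_length=h,
        params=params,
        param_tsv=param_tsv,
    )
    vols = mesh.element_volumes()
    if np.any(vols <= 1e-12):
        mesh.elements = mesh.elements[vols > 1e-12]
    mesh.validate()
    return mesh


def ring_index_arr(it, js, kv, n_s, n_v):
    return (it * (n_s - 1) + js) * n_v + kv


# ---------------------------------------------------------------------------
# universal ventricular coordinates
# ---------------------------------------------------------------------------


@dataclass
class UVCoordinates:
    """Per-node ventricular coordinates.

    z:   0 at the apex, 1 on the base plane (normalized graph distance).
    rho: 0 on the endocardium, 1 on the epicardium.
    phi: azimuth about the long axis in (-pi, pi], 0 at the septal reference.
    """

    z: np.ndarray
    rho: np.ndarray
    phi: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.z, self.rho, self.phi])


def _normalized_two_sided(graph: csr_matrix, seeds0, seeds1) -> np.ndarray:
    d0 = dijkstra(graph, directed=False, indices=seeds0, min_only=True)
    d1 = dijkstra(graph, directed=False, indices=seeds1, min_only=True)
    tot = d0 + d1
    tot[tot == 0] = 1.0
    return np.clip(d0 / tot, 0.0, 1.0)


def compute_uvc(
    mesh: VentricularMesh, septal_direction: Sequence[float] = (1.0, 0.0, 0.0)
) -> UVCoordinates:
    """Compute (z, rho, phi) for every mesh node.

    z and rho are normalized two-sided graph (geodesic) distances between
    the anchoring surfaces: z between the apex axis and the base plane, rho
    between the endocardial and epicardial surfaces; phi is the atan2
    azimuth about the long axis measured from ``septal_direction``.
    """
    lab = mesh.surface_label
    for needed in ("endo", "epi", "base"):
        if not np.any(lab == needed):
            raise ValueError(f"missing surface label class: {needed!r}")

    graph = mesh.edge_graph()
    axis = mesh.base_point - mesh.apex_point
    axis = axis / np.linalg.norm(axis)
    rel = mesh.node_coords - mesh.apex_point
    radial = rel - np.outer(rel @ axis, axis)
    on_axis = np.linalg.norm(radial, axis=1) < 1e-9

    apex_seeds = np.flatnonzero(on_axis)
    if apex_seeds.size == 0:
        apex_seeds = np.array(
            [np.argmin(np.linalg.norm(mesh.node_coords - mesh.apex_point, axis=1))]
        )
    base_seeds = np.flatnonzero(lab == "base")

    z = _normalized_two_sided(graph, apex_seeds, base_seeds)
    rho = _normalized_two_sided(
        graph, np.flatnonzero(lab == "endo"), np.flatnonzero(lab == "epi")
    )

    e1 = np.asarray(septal_direction, dtype=float)
    e1 = e1 - (e1 @ axis) * axis
    if np.linalg.norm(e1) < 1e-12:
        raise ValueError("septal_direction must not be parallel to the long axis")
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phi = np.arctan2(radial @ e2, radial @ e1)
    phi[on_axis] = 0.0
    phi = wrap_angle(phi)
    # map the -pi seam representative to +pi to honour the (-pi, pi] range
    phi[np.isclose(phi, -np.pi)] = np.pi
    return UVCoordinates(z=z, rho=rho, phi=phi)


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------


def assign_fibers(
    mesh: VentricularMesh,
    uvc: UVCoordinates,
    endo_angle: float = 60.0,
    epi_angle: float = -60.0,
) -> VentricularMesh:
    """Assign per-element fiber vectors with a linear transmural helix.

    The helix angle rotates linearly in rho from ``endo_angle`` (rho=0) to
    ``epi_angle`` (rho=1), measured from the local circumferential direction
    towards the apex-base direction.  Fibers are tangent to the wall: the
    local frame is built from the discrete gradients of rho (transmural
    normal) and z (apex-base direction) on each tetrahedron.
    """
    grads_rho = _element_gradients(mesh, uvc.rho)
    grads_z = _element_gradients(mesh, uvc.z)
    rho_el = uvc.rho[mesh.elements].mean(axis=1)

    n = _safe_normalize(grads_rho)
    # longitudinal: z gradient projected tangent to the wall
    el = grads_z - np.einsum("ij,ij->i", grads_z, n)[:, None] * n
    bad = np.linalg.norm(el, axis=1) < 1e-9
    if np.any(bad):
        # near the apex the z gradient can align with the wall normal; fall
        # back to any direction orthogonal to n
        fallback = np.cross(n[bad], np.array([1.0, 0.0, 0.0]))
        tiny = np.linalg.norm(fallback, axis=1) < 1e-9
        fallback[tiny] = np.cross(n[bad][tiny], np.array([0.0, 1.0, 0.0]))
        el[bad] = fallback
    el = _safe_normalize(el)
    ec = np.cross(n, el)
    ec = _safe_normalize(ec)

    alpha = np.deg2rad(endo_angle + (epi_angle - endo_angle) * rho_el)
    fiber = np.cos(alpha)[:, None] * ec + np.sin(alpha)[:, None] * el
    fiber = _safe_normalize(fiber)

    out = dataclasses.replace(mesh, fiber=fiber)
    out.validate()
    return out


def _safe_normalize(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return x / n


def _element_gradients(mesh: VentricularMesh, nodal: np.ndarray) -> np.ndarray:
    """Discrete gradient of a nodal scalar on each tetrahedron, (n_elem, 3)."""
    x = mesh.node_coords[mesh.elements]
    u = nodal[mesh.elements]
    d = x[:, 1:] - x[:, 0:1]  # (n_elem, 3, 3) edge matrix rows
    du = u[:, 1:] - u[:, 0:1]
    return np.linalg.solve(d, du[..., None])[..., 0]


# ---------------------------------------------------------------------------
# AHA segment models
# ---------------------------------------------------------------------------


@dataclass
class SegmentModel:
    """AHA 17/68 segment labels, per-(segment, surface) centres of gravity
    and segment adjacency, in the chosen ``mode`` (17 or 68).

    Numbering: basal ring (z in [2/3, 1]) segments 1-6 by 60 deg phi sector
    from -pi; mid ring (z in [1/3, 2/3)) segments 7-12; apical ring
    (z in [z_cap, 1/3)) segments 13-16 by 90 deg sector; apex cap
    (z < z_cap) segment 17.  The 68-segment model quarters each segment by
    halving its z and phi ranges (child = 4*(parent-1) + 2*z_half + phi_half
    + 1); the cap is split into its 4 phi quadrants (65-68), so
    seg17 == ceil(seg68 / 4).
    """

    mode: int
    seg17: np.ndarray
    seg68: np.ndarray
    cog: Dict[Tuple[int, str], np.ndarray]
    adjacency: Dict[int, FrozenSet[int]]
    z_cap: float = 0.1

    @property
    def labels(self) -> np.ndarray:
        return self.seg17 if self.mode == 17 else self.seg68

    @property
    def n_segments(self) -> int:
        return self.mode


def _seg17_labels(z: np.ndarray, phi: np.ndarray, z_cap: float) -> np.ndarray:
    sec6 = np.clip(((phi + np.pi) // (np.pi / 3)).astype(int), 0, 5)
    sec4 = np.clip(((phi + np.pi) // (np.pi / 2)).astype(int), 0, 3)
    out = np.empty(z.shape, dtype=int)
    basal = z >= 2.0 / 3.0
    mid = (z >= 1.0 / 3.0) & ~basal
    apical = (z >= z_cap) & ~basal & ~mid
    cap = z < z_cap
    out[basal] = 1 + sec6[basal]
    out[mid] = 7 + sec6[mid]
    out[apical] = 13 + sec4[apical]
    out[cap] = 17
    return out


def _seg68_labels(
    z: np.ndarray, phi: np.ndarray, seg17: np.ndarray, z_cap: float
) -> np.ndarray:
    out = np.empty(z.shape, dtype=int)
    p = phi + np.pi  # [0, 2pi)
    for s in range(1, 17):
        m = seg17 == s
        if not np.any(m):
            continue
        if s <= 6:
            z0, z1 = 2.0 / 3.0, 1.0
            width = np.pi / 3.0
            p0 = (s - 1) * width
        elif s <= 12:
            z0, z1 = 1.0 / 3.0, 2.0 / 3.0
            width = np.pi / 3.0
            p0 = (s - 7) * width
        else:
            z0, z1 = z_cap, 1.0 / 3.0
            width = np.pi / 2.0
            p0 = (s - 13) * width
        iz = (z[m] >= (z0 + z1) / 2.0).astype(int)
        ip = (p[m] - p0 >= width / 2.0).astype(int)
        out[m] = 4 * (s - 1) + 2 * iz + ip + 1
    cap = seg17 == 17
    quad = np.clip((p[cap] // (np.pi / 2.0)).astype(int), 0, 3)
    out[cap] = 65 + quad
    return out


def build_segment_model(
    mesh: VentricularMesh,
    uvc: UVCoordinates,
    mode: int = 17,
    z_cap: float = 0.1,
) -> SegmentModel:
    """Label every node with its AHA 17- and 68-segment ids and compute
    per-(segment, surface) centres of gravity and segment adjacency for
    ``mode``."""
    if mode not in (17, 68):
        raise ValueError("mode must be 17 or 68")
    seg17 = _seg17_labels(uvc.z, uvc.phi, z_cap)
    seg68 = _seg68_labels(uvc.z, uvc.phi, seg17, z_cap)
    labels = seg17 if mode == 17 else seg68

    missing = sorted(set(range(1, mode + 1)) - set(np.unique(labels)))
    if missing:
        raise ValueError(f"empty segments (mesh too coarse): {missing}")

    cog: Dict[Tuple[int, str], np.ndarray] = {}
    empties = []
    for surf in ("endo", "epi"):
        on = mesh.surface_label == surf
        for s in range(1, mode + 1):
            m = on & (labels == s)
            if not np.any(m):
                empties.append((s, surf))
                continue
            cog[(s, surf)] = mesh.node_coords[m].mean(axis=0)
    if empties:
        raise ValueError(f"segments with no surface nodes: {empties}")

    e = mesh.edges()
    la, lb = labels[e[:, 0]], labels[e[:, 1]]
    diff = la != lb
    adj: Dict[int, set] = {s: set() for s in range(1, mode + 1)}
    for a, b in zip(la[diff], lb[diff]):
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    adjacency = {s: frozenset(v) for s, v in adj.items()}
    return SegmentModel(
        mode=mode, seg17=seg17, seg68=seg68, cog=cog, adjacency=adjacency, z_cap=z_cap
    )


# ---------------------------------------------------------------------------
# electrodes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeParams:
    """Placement parameters for the 9 ECG electrodes and the 9 CIED sensing
    points, anchored to the LV geometry (all mm).

    The CIED emulates a device with a non-septal RV lead, an SVC coil, a can
    placed at the left-arm position (CAN = LA) and a straight 4-tip LV lead
    on the lateral epicardium with equal tip spacing.
    """

    lv_tip_spacing: float = 7.5
    precordial_radius: float = 120.0
    precordial_height: float = 50.0
    limb_distance: float = 180.0
    rv_offset: float = 4.0  # clearance of RV lead from the septal epicardium
    lv_offset: float = 3.0  # clearance of LV lead from the lateral epicardium

    def validate(self) -> None:
        if self.lv_tip_spacing <= 0:
            raise ValueError("lv_tip_spacing must be positive")


@dataclass
class ElectrodeSet:
    """Named electrode coordinates (mm)."""

    positions: Dict[str, np.ndarray]
    lv_tip_spacing: float

    def coords(self, names: Sequence[str]) -> np.ndarray:
        return np.stack([self.positions[n] for n in names])

    def displaced(self, vector_mm: Sequence[float], names: Sequence[str] = ECG_ELECTRODES) -> "ElectrodeSet":
        """Return a copy with ``names`` translated by ``vector_mm``."""
        v = np.asarray(vector_mm, dtype=float)
        pos = {k: (p + v if k in names else p.copy()) for k, p in self.positions.items()}
        return ElectrodeSet(positions=pos, lv_tip_spacing=self.lv_tip_spacing)

    def with_lv_spacing(self, spacing: float) -> "ElectrodeSet":
        """Return a copy with the 4 collinear LV tips re-spaced about tip 1."""
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        p1 = self.positions["LVtip1"]
        d = self.positions["LVtip2"] - p1
        d = d / np.linalg.norm(d)
        pos = dict(self.positions)
        for i in range(4):
            pos[f"LVtip{i + 1}"] = p1 + i * spacing * d
        return ElectrodeSet(positions=pos, lv_tip_spacing=spacing)

    def with_position(self, name: str, xyz: Sequence[float]) -> "ElectrodeSet":
        pos = dict(self.positions)
        pos[name] = np.asarray(xyz, dtype=float)
        return ElectrodeSet(positions=pos, lv_tip_spacing=self.lv_tip_spacing)

    def to_table(self) -> "np.ndarray":
        import pandas as pd

        rows = [(k, *p) for k, p in self.positions.items()]
        return pd.DataFrame(rows, columns=["name", "x_mm", "y_mm", "z_mm"])


def place_electrodes(
    params: ElectrodeParams = ElectrodeParams(),
    geometry: GeometryParams = GeometryParams(),
) -> ElectrodeSet:
    """Deterministic electrode coordinates for the default torso layout.

    Septal direction is +x (where the RV lead sits, just outside the LV
    epicardium); the LV lead runs superiorly along the lateral (-x)
    epicardium; precordial V1-V6 sweep an anterior arc at torso radius.
    """
    params.validate()
    a = geometry.epi_radius
    L = geometry.epi_length
    pos: Dict[str, np.ndarray] = {}

    angles = np.deg2rad([80.0, 60.0, 40.0, 20.0, 0.0, -20.0])  # V1..V6
    for name, ang in zip(("V1", "V2", "V3", "V4", "V5", "V6"), angles):
        pos[name] = np.array(
            [
                params.precordial_radius * np.cos(ang),
                params.precordial_radius * np.sin(ang),
                params.precordial_height,
            ]
        )
    d = params.limb_distance
    pos["RA"] = np.array([d, -d / 3.0, L + d])
    pos["LA"] = np.array([-d, -d / 3.0, L + d])
    pos["LL"] = np.array([-d / 1.5, -d / 3.0, -d])

    # RV lead just outside the epicardium, anterior of the septum (a standard
    # non-septal lead); the septal-coil sweep variant rotates the coil to +x
    r_rv = a + params.rv_offset
    ang_rv = np.deg2rad(40.0)
    c_rv, s_rv = np.cos(ang_rv), np.sin(ang_rv)
    pos["RVtip"] = np.array([r_rv * c_rv, r_rv * s_rv, 0.30 * L])
    pos["RVring"] = np.array([r_rv * c_rv, r_rv * s_rv, 0.30 * L + 10.0])
    pos["RVcoil"] = np.array([r_rv * c_rv, r_rv * s_rv, 0.55 * L])
    pos["SVC"] = np.array([10.0, 0.0, L + 60.0])
    pos["CAN"] = pos["LA"].copy()

    x_lv = -(a + params.lv_offset)
    for i in range(4):
        pos[f"LVtip{i + 1}"] = np.array(
            [x_lv, 0.0, 0.35 * L + i * params.lv_tip_spacing]
        )
    return ElectrodeSet(positions=pos, lv_tip_spacing=params.lv_tip_spacing)


# ---------------------------------------------------------------------------
# pacing-site sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PacingSite:
    node: int
    xyz: np.ndarray
    z: float
    rho: float
    phi: float
    wall_class: str  # endo | mid | epi


def sample_pacing_sites(
    mesh: VentricularMesh,
    uvc: UVCoordinates,
    n: int,
    proportions: Tuple[float, float, float] = (0.32, 0.36, 0.32),
    seed: int = 0,
) -> List[PacingSite]:
    """Sample ``n`` pacing sites stratified by wall class.

    ``proportions`` are (endo, mid, epi) fractions; counts are allocated by
    largest remainder so they sum exactly to ``n``.  Within each class,
    nodes are drawn without replacement with probability proportional to
    their incident element volume, approximating uniform spatial coverage
    on the non-uniform structured lattice.  Reproducible per seed.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    props = np.asarray(proportions, dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must sum to 1")

    lab = mesh.surface_label
    classes = {
        "endo": np.flatnonzero(lab == "endo"),
        "mid": np.flatnonzero(lab == ""),
        "epi": np.flatnonzero(lab == "epi"),
    }
    for name, idx in classes.items():
        if idx.size == 0:
            raise ValueError(f"no candidate nodes in wall class {name!r}")

    raw = n * props
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for k in np.argsort(-rem)[: n - counts.sum()]:
        counts[k] += 1

    # node weight ~ share of incident element volume
    vols = mesh.element_volumes()
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, mesh.elements.ravel(), np.repeat(vols / 4.0, 4))

    rng = np.random.default_rng(seed)
    sites: List[PacingSite] = []
    for name, count in zip(("endo", "mid", "epi"), counts):
        idx = classes[name]
        if count > idx.size:
            raise ValueError(f"wall class {name!r} has only {idx.size} candidate nodes")
        p = w[idx] / w[idx].sum()
        chosen = rng.choice(idx, size=count, replace=False, p=p)
        for node in np.sort(chosen):
            node = int(node)
            sites.append(
                PacingSite(
                    node=node,
                    xyz=mesh.node_coords[node].copy(),
                    z=float(uvc.z[node]),
                    rho=float(uvc.rho[node]),
                    phi=float(uvc.phi[node]),
                    wall_class=name,
                )
            )
    return sites
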