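"""Infinite-medium lead fields and pseudo-ECG/EGM source integration.

Each electrode ``e`` at ``x_e`` has the scalar kernel

    Z_e(x) = 1 / (4 pi sigma_bath |x - x_e|)

evaluated at element centroids.  Extracellular potentials follow the
volume-conductor source integral

    phi_e(t) = sum_elements sigma_intra * grad(Vm) . grad(Z_e) * vol,

with per-tetrahedron discrete gradients.  Because the integral is linear in
the nodal Vm, it collapses to a precomputed transfer matrix M
(electrodes x nodes), so a whole beat is one matrix product M @ Vm(t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .geometry import ElectrodeSet, VentricularMesh, _element_gradients

__all__ = [
    "LeadFieldMatrix",
    "compute_lead_field",
    "kernel",
    "kernel_gradient",
    "compute_extracellular",
    "build_transfer_matrix",
    "average_tip_cloud",
    "with_tip_cloud",
    "perturb_leadfield",
    "sphere_points",
]

logger = logging.getLogger(__name__)

MIN_ELECTRODE_CLEARANCE_MM = 0.5


def kernel(points: np.ndarray, electrode: np.ndarray, sigma_bath: float) -> np.ndarray:
    """Point-source kernel Z(x) = 1/(4 pi sigma r) at ``points``."""
    r = np.linalg.norm(points - electrode, axis=-1)
    return 1.0 / (4.0 * np.pi * sigma_bath * r)


def kernel_gradient(
    points: np.ndarray, electrode: np.ndarray, sigma_bath: float
) -> np.ndarray:
    """grad_x Z(x) = (x_e - x) / (4 pi sigma r^3)."""
    d = electrode - points
    r = np.linalg.norm(d, axis=-1, keepdims=True)
    return d / (4.0 * np.pi * sigma_bath * r**3)


@dataclass
class LeadFieldMatrix:
    """Per-electrode kernel weights at element centroids.

    ``weights[i, j]`` is Z for electrode ``electrode_order[i]`` at element
    ``j``'s centroid. ``electrode_positions`` retains the effective sensing
    points (rows averaged over a tip cloud store the cloud's points in
    ``clouds``), so kernel gradients can be re-evaluated for the source
    integral.
    """

    weights: np.ndarray  # (n_elec, n_elem)
    electrode_order: tuple
    electrode_positions: np.ndarray  # (n_elec, 3)
    sigma_bath: float
    element_volumes: np.ndarray  # (n_elem,)
    clouds: Dict[str, np.ndarray] = field(default_factory=dict)
    row_scale: Optional[np.ndarray] = None  # surrogate perturbation factors
    surrogate_note: str = ""

    def row(self, name: str) -> np.ndarray:
        return self.weights[self.electrode_order.index(name)]


def compute_lead_field(
    mesh: VentricularMesh,
    electrodes: ElectrodeSet,
    sigma_bath: float,
    order: Optional[Sequence[str]] = None,
) -> LeadFieldMatrix:
    """Evaluate the infinite-medium kernel for every electrode at every
    element centroid.  Computed once per electrode configuration."""
    if sigma_bath <= 0:
        raise ValueError("sigma_bath must be positive")
    names = tuple(order) if order is not None else tuple(electrodes.positions)
    pos = electrodes.coords(names)
    cent = mesh.element_centroids()
    dists = np.linalg.norm(cent[None, :, :] - pos[:, None, :], axis=2)
    too_close = dists.min(axis=1) < MIN_ELECTRODE_CLEARANCE_MM
    if np.any(too_close):
        bad = [names[i] for i in np.flatnonzero(too_close)]
        raise ValueError(
            f"electrodes within {MIN_ELECTRODE_CLEARANCE_MM} mm of an element "
            f"centroid (singular kernel): {bad}"
        )
    weights = 1.0 / (4.0 * np.pi * sigma_bath * dists)
    return LeadFieldMatrix(
        weights=weights,
        electrode_order=names,
        electrode_positions=pos,
        sigma_bath=sigma_bath,
        element_volumes=mesh.element_volumes(),
    )


def build_transfer_matrix(
    lf: LeadFieldMatrix, mesh: VentricularMesh, sigma_intra: float
) -> np.ndarray:
    """Dense transfer matrix M (n_elec x n_nodes): phi(t) = M @ Vm(:, t).

    M_e,n = sum_over elements containing n of
            sigma_intra * vol * grad(Z_e) . g_n
    with g_n the element shape-function gradient of node n.
    """
    x = mesh.node_coords[mesh.elements]  # (E, 4, 3)
    d = x[:, 1:] - x[:, 0:1]  # (E, 3, 3)
    dinv = np.linalg.inv(d)  # columns map du -> grad
    # grad u = dinv^T? — consistent with _element_gradients: grad = solve(d, du)
    # shape-function gradients: G (E, 3, 4) with grad u = G @ u_local
    G = np.empty((mesh.n_elements, 3, 4))
    G[:, :, 1:] = dinv
    G[:, :, 0] = -dinv.sum(axis=2)

    vols = lf.element_volumes
    n_elec = len(lf.electrode_order)
    M = np.zeros((n_elec, mesh.n_nodes))
    cent = mesh.element_centroids()
    scale = lf.row_scale if lf.row_scale is not None else np.ones(n_elec)
    for i, name in enumerate(lf.electrode_order):
        pts = lf.clouds.get(name)
        if pts is None:
            gz = kernel_gradient(cent, lf.electrode_positions[i], lf.sigma_bath)
        else:
            gz = np.mean(
                [kernel_gradient(cent, p, lf.sigma_bath) for p in pts], axis=0
            )
        # per-element row: sigma_i * vol * gz . G  -> (E, 4) nodal weights
        contrib = sigma_intra * vols[:, None] * np.einsum("ej,eji->ei", gz, G)
        row = np.zeros(mesh.n_nodes)
        np.add.at(row, mesh.elements.ravel(), contrib.ravel())
        M[i] = scale[i] * row
    return M


def compute_extracellular(
    lf: LeadFieldMatrix,
    vm: np.ndarray,
    mesh: VentricularMesh,
    sigma_intra: float,
    transfer: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Extracellular traces (n_elec, n_times) from a Vm movie
    (n_nodes, n_times)."""
    if vm.shape[0] != mesh.n_nodes:
        raise ValueError(
            f"Vm movie has {vm.shape[0]} nodes but mesh has {mesh.n_nodes}"
        )
    M = transfer if transfer is not None else build_transfer_matrix(lf, mesh, sigma_intra)
    return M @ vm


def sphere_points(radius: float, n_points: int, center: np.ndarray) -> np.ndarray:
    """Deterministic quasi-uniform points inside a sphere (Fibonacci lattice
    mapped radially)."""
    i = np.arange(n_points) + 0.5
    u = i / n_points  # radial cdf
    r = radius * u ** (1.0 / 3.0)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    zc = 1.0 - 2.0 * u
    rho = np.sqrt(np.clip(1.0 - zc**2, 0.0, 1.0))
    pts = np.column_stack([rho * np.cos(ga * i), rho * np.sin(ga * i), zc])
    return center + r[:, None] * pts


def average_tip_cloud(
    mesh: VentricularMesh,
    lf: LeadFieldMatrix,
    electrode: str,
    radius_mm: float,
    n_points: int = 32,
) -> np.ndarray:
    """Effective lead-field row for a finite-size tip: mean of the point
    kernel over a quasi-uniform cloud inside the sphere of ``radius_mm``.

    Cloud points closer than the clearance bound to any element centroid are
    excluded with a logged warning; reduces to the point row as radius -> 0.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    i = lf.electrode_order.index(electrode)
    center = lf.electrode_positions[i]
    if radius_mm == 0 or n_points == 1:
        return lf.weights[i].copy()
    pts = sphere_points(radius_mm, n_points, center)
    cent = mesh.element_centroids()
    rows = []
    for p in pts:
        dmin = np.linalg.norm(cent - p, axis=1).min()
        if dmin < MIN_ELECTRODE_CLEARANCE_MM:
            logger.warning(
                "tip-cloud point at %s excluded (%.2f mm from an element centroid)",
                p,
                dmin,
            )
            continue
        rows.append(kernel(cent, p, lf.sigma_bath))
    if not rows:
        raise ValueError("all cloud points excluded; electrode too close to tissue")
    return np.mean(rows, axis=0)


def with_tip_cloud(
    mesh: VentricularMesh,
    lf: LeadFieldMatrix,
    electrodes: Sequence[str],
    radius_mm: float,
    n_points: int = 32,
) -> LeadFieldMatrix:
    """Copy of ``lf`` with the given electrodes replaced by ``radius_mm``
    tip-cloud averages (both the Z rows and the source-integral geometry)."""
    weights = lf.weights.copy()
    clouds = dict(lf.clouds)
    for name in electrodes:
        i = lf.electrode_order.index(name)
        weights[i] = average_tip_cloud(mesh, lf, name, radius_mm, n_points)
        clouds[name] = sphere_points(radius_mm, n_points, lf.electrode_positions[i])
    return LeadFieldMatrix(
        weights=weights,
        electrode_order=lf.electrode_order,
        electrode_positions=lf.electrode_positions.copy(),
        sigma_bath=lf.sigma_bath,
        element_volumes=lf.element_volumes,
        clouds=clouds,
        row_scale=None if lf.row_scale is None else lf.row_scale.copy(),
        surrogate_note=lf.surrogate_note,
    )


def perturb_leadfield(
    lf: LeadFieldMatrix, scale_map: Mapping[str, float], seed: int = 0
) -> LeadFieldMatrix:
    """Surrogate lead-field perturbation: multiply electrode rows by fixed
    factors.

    This is an explicit *surrogate* for torso-conductivity variation (which
    would require a heterogeneous volume conductor); it is labelled as such
    in the returned object and in logs.  ``scale_map`` maps electrode names
    (or "*" for all) to positive factors.  Deterministic: ``seed`` is only
    consumed if a future factor-sampling hook is added.
    """
    factors = np.ones(len(lf.electrode_order))
    for key, val in scale_map.items():
        if val <= 0:
            raise ValueError(f"non-positive factor for {key!r}: {val}")
        if key == "*":
            factors[:] = val
        else:
            factors[lf.electrode_order.index(key)] = val
    note = "surrogate lead-field perturbation (homogeneous-medium stand-in)"
    logger.info("%s: factors=%s", note, dict(scale_map))
    base = lf.row_scale if lf.row_scale is not None else np.ones_like(factors)
    return LeadFieldMatrix(
        weights=lf.weights * factors[:, None],
        electrode_order=lf.electrode_order,
        electrode_positions=lf.electrode_positions.copy(),
        sigma_bath=lf.sigma_bath,
        element_volumes=lf.element_volumes,
        clouds=dict(lf.clouds),
        row_scale=base * factors,
        surrogate_note=note,
    )
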