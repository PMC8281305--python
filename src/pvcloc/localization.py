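"""From network outputs to Cartesian source estimates and scores.

Two schemes:

* Cartesian probability-based: the Segment CNN's probabilities, restricted
  to the most probable segment and its neighbours and renormalized, weight
  the per-segment endocardial/epicardial centres of gravity

      S_out = sum_{i in S} P_seg,i * (P_endo CoG_i,endo + P_epi CoG_i,epi),

  a convex combination of the participating CoGs.

* UVC-based: regression gives (z, rho), the wedge classifier gives phi; the
  triple is inverted to Cartesian space by the mesh node minimizing a
  millimetre-scaled UVC metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .geometry import SegmentModel, UVCoordinates, VentricularMesh, wrap_angle

__all__ = [
    "LocalizationResult",
    "cartesian_combine",
    "uvc_metric_weights",
    "uvc_to_cartesian",
    "localization_error",
    "score_segment_classifier",
    "bullseye_coords",
]


@dataclass
class LocalizationResult:
    predicted_xyz: np.ndarray
    truth_xyz: np.ndarray
    error_mm: float
    scheme: str  # cartesian17 | cartesian68 | uvc
    predicted_uvc: Optional[Tuple[float, float, float]] = None
    truth_uvc: Optional[Tuple[float, float, float]] = None
    beat_id: Optional[int] = None
    modality: Optional[str] = None


def cartesian_combine(
    p_seg: np.ndarray, p_epiendo: np.ndarray, segmodel: SegmentModel
) -> np.ndarray:
    """Probability–CoG combination over the argmax segment and its
    neighbours (renormalized), blending endo and epi surfaces by the
    EpiEndo probabilities.  ``p_epiendo`` is ordered (endo, epi)."""
    p_seg = np.asarray(p_seg, dtype=float)
    p_epiendo = np.asarray(p_epiendo, dtype=float)
    if p_seg.shape != (segmodel.n_segments,):
        raise ValueError(
            f"p_seg length {p_seg.shape} does not match {segmodel.n_segments} segments"
        )
    if p_epiendo.shape != (2,):
        raise ValueError("p_epiendo must have length 2 (endo, epi)")
    if abs(p_seg.sum() - 1.0) > 1e-6 or abs(p_epiendo.sum() - 1.0) > 1e-6:
        raise ValueError("probability vectors must sum to 1")
    if np.any(p_seg < -1e-12) or np.any(p_epiendo < -1e-12):
        raise ValueError("probabilities must be nonnegative")

    top = int(np.argmax(p_seg)) + 1
    members = sorted({top} | set(segmodel.adjacency[top]))
    w = p_seg[[s - 1 for s in members]]
    w = w / w.sum()
    out = np.zeros(3)
    for wi, s in zip(w, members):
        out += wi * (
            p_epiendo[0] * segmodel.cog[(s, "endo")]
            + p_epiendo[1] * segmodel.cog[(s, "epi")]
        )
    return out


def uvc_metric_weights(mesh: VentricularMesh, uvc: UVCoordinates) -> Tuple[float, float, float]:
    """(w_z, w_rho, w_phi): squared length scales converting unit changes of
    each coordinate to approximate millimetres — the apex-to-base extent for
    z, the wall thickness for rho and the mean mid-wall cylindrical radius
    for phi (arc length = radius * dphi)."""
    if mesh.params is not None:
        length = mesh.params.epi_length
        wall = mesh.params.wall_thickness
    else:
        length = float(mesh.node_coords[:, 2].ptp())
        axis_dist = np.linalg.norm(mesh.node_coords[:, :2], axis=1)
        wall = float(axis_dist.max() - axis_dist.min())
    radius = float(np.linalg.norm(mesh.node_coords[:, :2], axis=1).mean())
    return length**2, wall**2, radius**2


def uvc_to_cartesian(
    uvc_point: Sequence[float],
    mesh: VentricularMesh,
    node_uvc: UVCoordinates,
    weights: Optional[Tuple[float, float, float]] = None,
) -> Tuple[np.ndarray, int]:
    """Nearest mesh node to a (z, rho, phi) triple under the scaled metric

        d^2 = w_z dz^2 + w_rho drho^2 + w_phi wrap(dphi)^2.

    Returns (coordinates, node index)."""
    if mesh.n_nodes == 0:
        raise ValueError("empty mesh")
    z, rho, phi = (float(v) for v in uvc_point)
    if weights is None:
        weights = uvc_metric_weights(mesh, node_uvc)
    wz, wr, wp = weights
    dphi = wrap_angle(node_uvc.phi - phi)
    d2 = (
        wz * (node_uvc.z - z) ** 2
        + wr * (node_uvc.rho - rho) ** 2
        + wp * np.asarray(dphi) ** 2
    )
    node = int(np.argmin(d2))
    return mesh.node_coords[node].copy(), node


def localization_error(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Euclidean distance in millimetres."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(pred - truth))


def score_segment_classifier(
    predictions: Sequence[int], truths: Sequence[int], n_classes: int
) -> Tuple[float, Dict[int, Optional[float]]]:
    """Overall accuracy (percent of beats classified into the correct
    segment) and per-segment precision (correct predictions of a segment
    over all predictions of it; ``None`` where the segment was never
    predicted)."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    accuracy = 100.0 * float(np.mean(predictions == truths))
    precision: Dict[int, Optional[float]] = {}
    for s in range(1, n_classes + 1):
        pred_s = predictions == s
        precision[s] = (
            float(np.mean(truths[pred_s] == s)) if np.any(pred_s) else None
        )
    return accuracy, precision


def bullseye_coords(
    uvc_point: Sequence[float],
    ring_radii: Tuple[float, float, float] = (1.0 / 3.0, 2.0 / 3.0, 1.0),
) -> Tuple[float, float, float]:
    """2D bull's-eye position (r, theta) for a UVC triple.

    The radius grows piecewise-linearly with z across the apical/mid/basal
    rings (apex z=0 at the centre, base z=1 on the rim); theta = phi; rho is
    returned as a display attribute (colour), not a position."""
    z, rho, phi = (float(v) for v in uvc_point)
    z_edges = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)
    r_edges = (0.0, *ring_radii)
    z = min(max(z, 0.0), 1.0)
    for k in range(3):
        if z <= z_edges[k + 1] or k == 2:
            frac = (z - z_edges[k]) / (z_edges[k + 1] - z_edges[k])
            r = r_edges[k] + frac * (r_edges[k + 1] - r_edges[k])
            break
    return r, phi, rho
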