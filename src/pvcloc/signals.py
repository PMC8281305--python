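"""ECG/EGM channel derivation, QRS windowing, 16x16 matrices and datasets.

Sixteen channels are derived per modality:

ECG (from the 9 electrode potentials V1..V6, RA, LA, LL):
    1-12  : I, II, III, aVR, aVL, aVF, V1..V6 (precordials referenced to the
            Wilson central terminal (RA+LA+LL)/3),
    13-16 : the literal electrode arithmetic LL-RA-LA, LA-RA-LL, RA-LA-LL
            and (RA+LA+LL)/2.

EGM (from the 9 CIED sensing points):
    far-field CAN-SVC, CAN-RVcoil, SVC-RVcoil; near-field RVtip-RVring and
    LVtip_i - RVtip (i=1..4); plus CAN-LVtip_i and SVC-LVtip_i (i=1..4).

The QRS window is [0, max(tau) + upstroke + margin]; each channel is
resampled to 16 uniformly spaced points (endpoints inclusive) and the 16
channels stacked into a 16x16 matrix.  Noise is added per channel at a
prescribed SNR *before* max-abs normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .eikonal import APTemplate, ActivationMap
from .geometry import PacingSite

__all__ = [
    "ECG_CHANNELS",
    "EGM_CHANNELS",
    "TraceSet",
    "SignalMatrix",
    "BeatRecord",
    "Dataset",
    "derive_ecg_channels",
    "derive_egm_channels",
    "extract_qrs",
    "resample_16",
    "add_noise",
    "normalize_matrix",
    "augment",
    "phi_to_wedge",
    "wedge_to_phi",
    "build_dataset",
    "N_WEDGES",
    "WEDGE_WIDTH",
]

logger = logging.getLogger(__name__)

ECG_CHANNELS = (
    "I",
    "II",
    "III",
    "aVR",
    "aVL",
    "aVF",
    "V1",
    "V2",
    "V3",
    "V4",
    "V5",
    "V6",
    "LL-RA-LA",
    "LA-RA-LL",
    "RA-LA-LL",
    "(RA+LA+LL)/2",
)

EGM_CHANNELS = (
    "CAN-SVC",
    "CAN-RVcoil",
    "SVC-RVcoil",
    "RVtip-RVring",
    "LVtip1-RVtip",
    "LVtip2-RVtip",
    "LVtip3-RVtip",
    "LVtip4-RVtip",
    "CAN-LVtip1",
    "CAN-LVtip2",
    "CAN-LVtip3",
    "CAN-LVtip4",
    "SVC-LVtip1",
    "SVC-LVtip2",
    "SVC-LVtip3",
    "SVC-LVtip4",
)

N_WEDGES = 68
WEDGE_WIDTH = 2.0 * np.pi / N_WEDGES  # 0.0924 rad, "0.09" to two decimals

N_SAMPLES = 16


@dataclass
class TraceSet:
    """Named time traces on a common uniform grid."""

    names: Tuple[str, ...]
    values: np.ndarray  # (n_channels, n_times)
    times: np.ndarray  # (n_times,) ms

    def get(self, name: str) -> np.ndarray:
        return self.values[self.names.index(name)]


@dataclass
class SignalMatrix:
    """A 16x16 QRS matrix (channels x time samples), max-abs normalized."""

    values: np.ndarray
    modality: str  # "ecg" | "egm"
    channel_order: Tuple[str, ...]
    normalization: float
    snr_db: Optional[float] = None

    def __post_init__(self):
        if self.values.shape != (N_SAMPLES, N_SAMPLES):
            raise ValueError(f"matrix must be 16x16, got {self.values.shape}")


@dataclass
class BeatRecord:
    """One simulated paced beat: source labels plus raw (unnormalized) ECG
    and EGM 16x16 matrices.  Normalized/noised :class:`SignalMatrix` views
    are derived on demand so noise is always added on the raw scale."""

    beat_id: int
    site: PacingSite
    seg17: int
    seg68: int
    wedge: int
    raw_ecg: np.ndarray  # (16, 16) pre-normalization
    raw_egm: np.ndarray
    parent_id: Optional[int] = None  # set on augmented copies

    def raw(self, modality: str) -> np.ndarray:
        if modality == "ecg":
            return self.raw_ecg
        if modality == "egm":
            return self.raw_egm
        raise ValueError(f"unknown modality {modality!r}")

    def matrix(
        self, modality: str, snr_db: Optional[float] = None, rng=None
    ) -> SignalMatrix:
        raw = self.raw(modality)
        if snr_db is not None and np.isfinite(snr_db):
            if rng is None:
                raise ValueError("rng required when adding noise")
            raw = add_noise(raw, snr_db, rng)
        vals, scale = normalize_matrix(raw)
        return SignalMatrix(
            values=vals,
            modality=modality,
            channel_order=ECG_CHANNELS if modality == "ecg" else EGM_CHANNELS,
            normalization=scale,
            snr_db=snr_db,
        )


# ---------------------------------------------------------------------------
# channel derivation
# ---------------------------------------------------------------------------


def _require(traces: TraceSet, names: Sequence[str]) -> None:
    missing = [n for n in names if n not in traces.names]
    if missing:
        raise ValueError(f"missing electrode trace(s): {missing}")


def derive_ecg_channels(traces: TraceSet) -> TraceSet:
    """Sixteen ECG channels from the 9 electrode potentials."""
    _require(traces, ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6"))
    ra, la, ll = traces.get("RA"), traces.get("LA"), traces.get("LL")
    wct = (ra + la + ll) / 3.0
    chans = [
        la - ra,  # I
        ll - ra,  # II
        ll - la,  # III
        ra - (la + ll) / 2.0,  # aVR
        la - (ra + ll) / 2.0,  # aVL
        ll - (ra + la) / 2.0,  # aVF
    ]
    chans += [traces.get(f"V{i}") - wct for i in range(1, 7)]
    chans += [ll - ra - la, la - ra - ll, ra - la - ll, (ra + la + ll) / 2.0]
    return TraceSet(names=ECG_CHANNELS, values=np.stack(chans), times=traces.times)


def derive_egm_channels(traces: TraceSet) -> TraceSet:
    """Sixteen implanted-device EGM vectors."""
    _require(
        traces,
        ("CAN", "SVC", "RVcoil", "RVtip", "RVring", "LVtip1", "LVtip2", "LVtip3", "LVtip4"),
    )
    g = traces.get
    chans = [
        g("CAN") - g("SVC"),
        g("CAN") - g("RVcoil"),
        g("SVC") - g("RVcoil"),
        g("RVtip") - g("RVring"),
    ]
    chans += [g(f"LVtip{i}") - g("RVtip") for i in range(1, 5)]
    chans += [g("CAN") - g(f"LVtip{i}") for i in range(1, 5)]
    chans += [g("SVC") - g(f"LVtip{i}") for i in range(1, 5)]
    return TraceSet(names=EGM_CHANNELS, values=np.stack(chans), times=traces.times)


# ---------------------------------------------------------------------------
# QRS extraction, resampling, noise
# ---------------------------------------------------------------------------


def qrs_window_ms(
    activation: ActivationMap, template: APTemplate, margin_ms: float = 2.0
) -> float:
    if margin_ms < 0:
        raise ValueError("margin must be >= 0")
    return activation.max_tau() + template.upstroke_ms + margin_ms


def extract_qrs(
    traces: TraceSet,
    activation: ActivationMap,
    template: APTemplate,
    margin_ms: float = 2.0,
) -> TraceSet:
    """Window all channels of a beat to [0, max(tau) + upstroke + margin]."""
    end = qrs_window_ms(activation, template, margin_ms)
    if end > traces.times[-1] + 1e-9:
        raise ValueError(
            f"QRS window {end:.2f} ms exceeds simulated duration "
            f"{traces.times[-1]:.2f} ms"
        )
    keep = traces.times <= end + 1e-9
    return TraceSet(
        names=traces.names, values=traces.values[:, keep], times=traces.times[keep]
    )


def resample_16(traces: TraceSet) -> np.ndarray:
    """Linear interpolation of every channel at 16 uniform times spanning
    the window, endpoints inclusive; returns (n_channels, 16)."""
    if traces.values.shape[1] < 2:
        raise ValueError("trace must have at least 2 samples")
    tq = np.linspace(traces.times[0], traces.times[-1], N_SAMPLES)
    return np.stack([np.interp(tq, traces.times, ch) for ch in traces.values])


def add_noise(values: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    """Additive per-channel white Gaussian noise at ``snr_db``.

    Noise variance per channel = mean-square of the clean channel divided by
    10^(snr/10).  Channels with zero power get zero noise (logged)."""
    values = np.asarray(values, dtype=float)
    if np.isinf(snr_db):
        return values.copy()
    power = np.mean(values**2, axis=-1)
    if np.any(power == 0):
        logger.warning(
            "zero-power channel(s) %s: noise variance set to 0",
            np.flatnonzero(power == 0).tolist(),
        )
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    return values + sigma[..., None] * rng.standard_normal(values.shape)


def normalize_matrix(values: np.ndarray) -> Tuple[np.ndarray, float]:
    """Max-abs normalization; returns (normalized, scale)."""
    scale = float(np.max(np.abs(values)))
    if scale == 0:
        return values.copy(), 0.0
    return values / scale, scale


# ---------------------------------------------------------------------------
# phi wedges
# ---------------------------------------------------------------------------


def phi_to_wedge(phi: float) -> int:
    """Class 1..68 for phi in [-pi, pi]; wedge k covers
    [-pi + (k-1) w, -pi + k w) with w = 2 pi / 68; phi = pi maps to 68."""
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < -np.pi - 1e-12) or np.any(phi_arr > np.pi + 1e-12):
        raise ValueError(f"phi outside [-pi, pi]: {phi}")
    k = np.floor((phi_arr + np.pi) / WEDGE_WIDTH).astype(int) + 1
    k = np.clip(k, 1, N_WEDGES)
    return k if k.ndim else int(k)


def wedge_to_phi(k) -> float:
    """Centre angle of wedge ``k``."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 1) or np.any(k_arr > N_WEDGES):
        raise ValueError(f"wedge class out of range 1..{N_WEDGES}: {k}")
    out = -np.pi + (k_arr - 0.5) * WEDGE_WIDTH
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Train/test split of beat records with augmentation bookkeeping."""

    train: List[BeatRecord]
    test: List[BeatRecord]
    seed: int
    augmentation_k: int = 1
    snr_db: Optional[float] = None

    def epiendo_train(self) -> List[BeatRecord]:
        """Training view for the endo-vs-epi classifier: surface beats only."""
        return [r for r in self.train if r.site.wall_class != "mid"]

    def matrices(
        self,
        split: str,
        modality: str,
        snr_db: Optional[float] = None,
        rng=None,
        records: Optional[List[BeatRecord]] = None,
    ) -> np.ndarray:
        """Stacked normalized matrices (n, 16, 16) for a split."""
        recs = records if records is not None else getattr(self, split)
        return np.stack(
            [r.matrix(modality, snr_db=snr_db, rng=rng).values for r in recs]
        )

    @staticmethod
    def labels(records: List[BeatRecord], task: str) -> np.ndarray:
        if task == "segment17":
            return np.array([r.seg17 for r in records])
        if task == "segment68":
            return np.array([r.seg68 for r in records])
        if task == "epiendo":
            return np.array(
                [0 if r.site.wall_class == "endo" else 1 for r in records]
            )
        if task == "uvc_regression":
            return np.array([[r.site.z, r.site.rho] for r in records])
        if task == "phi_classification":
            return np.array([r.wedge for r in records])
        raise ValueError(f"unknown task {task!r}")


def build_dataset(
    beats: List[BeatRecord], n_train: int, n_test: int, seed: int
) -> Dataset:
    """Random disjoint train/test split of simulated beats."""
    if n_train + n_test > len(beats):
        raise ValueError(
            f"need {n_train + n_test} beats but only {len(beats)} available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(beats))
    train = [beats[i] for i in order[:n_train]]
    test = [beats[i] for i in order[n_train : n_train + n_test]]
    return Dataset(train=train, test=test, seed=seed)


def augment(
    dataset: Dataset, k: int, snr_db: float, rng: np.random.Generator
) -> Dataset:
    """Replace each training record by ``k`` independently noised copies.

    Noise is added to the raw matrices, which are then re-normalized when a
    matrix view is requested.  Applies to the train split only; augmented
    copies inherit their parent's labels and never cross into the test
    split."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out: List[BeatRecord] = []
    next_id = max((r.beat_id for r in dataset.train + dataset.test), default=0) + 1
    for rec in dataset.train:
        for _ in range(k):
            out.append(
                replace(
                    rec,
                    beat_id=next_id,
                    raw_ecg=add_noise(rec.raw_ecg, snr_db, rng),
                    raw_egm=add_noise(rec.raw_egm, snr_db, rng),
                    parent_id=rec.beat_id,
                )
            )
            next_id += 1
    return Dataset(
        train=out,
        test=dataset.test,
        seed=dataset.seed,
        augmentation_k=k,
        snr_db=snr_db,
    )
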