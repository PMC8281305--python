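"""Array-container persistence for beats, datasets and trained models.

Beats and datasets go into a single ``.npz`` (arrays + label columns, with
the split manifest also exportable as CSV); models into one ``.npz`` per
(task, modality) plus a JSON sidecar with the spec, seed and loss history.
Round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import PacingSite
from .networks import NetworkSpec, TrainedModel
from .signals import BeatRecord, Dataset

__all__ = [
    "save_beats",
    "load_beats",
    "save_dataset",
    "load_dataset",
    "save_models",
    "load_models",
    "dataset_manifest",
    "leadfield_cache_key",
    "save_leadfield",
    "load_leadfield",
]

_WALL_CODE = {"endo": 0, "mid": 1, "epi": 2}
_CODE_WALL = {v: k for k, v in _WALL_CODE.items()}


def _records_arrays(records: List[BeatRecord]) -> Dict[str, np.ndarray]:
    return {
        "beat_id": np.array([r.beat_id for r in records], dtype=np.int64),
        "parent_id": np.array(
            [-1 if r.parent_id is None else r.parent_id for r in records],
            dtype=np.int64,
        ),
        "node": np.array([r.site.node for r in records], dtype=np.int64),
        "xyz": np.stack([r.site.xyz for r in records]) if records else np.zeros((0, 3)),
        "uvc": np.array([[r.site.z, r.site.rho, r.site.phi] for r in records]),
        "wall": np.array([_WALL_CODE[r.site.wall_class] for r in records], dtype=np.int64),
        "seg17": np.array([r.seg17 for r in records], dtype=np.int64),
        "seg68": np.array([r.seg68 for r in records], dtype=np.int64),
        "wedge": np.array([r.wedge for r in records], dtype=np.int64),
        "raw_ecg": np.stack([r.raw_ecg for r in records]),
        "raw_egm": np.stack([r.raw_egm for r in records]),
    }


def _arrays_records(d, idx) -> List[BeatRecord]:
    out = []
    for i in idx:
        site = PacingSite(
            node=int(d["node"][i]),
            xyz=d["xyz"][i].copy(),
            z=float(d["uvc"][i, 0]),
            rho=float(d["uvc"][i, 1]),
            phi=float(d["uvc"][i, 2]),
            wall_class=_CODE_WALL[int(d["wall"][i])],
        )
        pid = int(d["parent_id"][i])
        out.append(
            BeatRecord(
                beat_id=int(d["beat_id"][i]),
                site=site,
                seg17=int(d["seg17"][i]),
                seg68=int(d["seg68"][i]),
                wedge=int(d["wedge"][i]),
                raw_ecg=d["raw_ecg"][i].copy(),
                raw_egm=d["raw_egm"][i].copy(),
                parent_id=None if pid < 0 else pid,
            )
        )
    return out


def save_beats(path, beats: List[BeatRecord]) -> None:
    np.savez_compressed(path, **_records_arrays(beats))


def load_beats(path) -> List[BeatRecord]:
    with np.load(path) as d:
        d = {k: d[k] for k in d.files}
    return _arrays_records(d, range(len(d["beat_id"])))


def save_dataset(path, dataset: Dataset) -> None:
    recs = dataset.train + dataset.test
    arrays = _records_arrays(recs)
    arrays["is_train"] = np.array(
        [1] * len(dataset.train) + [0] * len(dataset.test), dtype=np.int64
    )
    arrays["meta"] = np.array(
        [
            dataset.seed,
            dataset.augmentation_k,
            np.nan if dataset.snr_db is None else dataset.snr_db,
        ]
    )
    np.savez_compressed(path, **arrays)


def load_dataset(path) -> Dataset:
    with np.load(path) as d:
        d = {k: d[k] for k in d.files}
    train_idx = np.flatnonzero(d["is_train"] == 1)
    test_idx = np.flatnonzero(d["is_train"] == 0)
    seed, k, snr = d["meta"]
    return Dataset(
        train=_arrays_records(d, train_idx),
        test=_arrays_records(d, test_idx),
        seed=int(seed),
        augmentation_k=int(k),
        snr_db=None if np.isnan(snr) else float(snr),
    )


def dataset_manifest(dataset: Dataset) -> pd.DataFrame:
    """Delimited-table manifest: beat id, split, labels, site xyz/UVC."""
    rows = []
    for split, recs in (("train", dataset.train), ("test", dataset.test)):
        for r in recs:
            rows.append(
                {
                    "beat_id": r.beat_id,
                    "split": split,
                    "parent_id": r.parent_id,
                    "wall_class": r.site.wall_class,
                    "seg17": r.seg17,
                    "seg68": r.seg68,
                    "wedge": r.wedge,
                    "x_mm": r.site.xyz[0],
                    "y_mm": r.site.xyz[1],
                    "z_mm": r.site.xyz[2],
                    "uvc_z": r.site.z,
                    "uvc_rho": r.site.rho,
                    "uvc_phi": r.site.phi,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def save_models(out_dir, models: Dict[Tuple[str, str], TrainedModel]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (task, modality), model in models.items():
        stem = out / f"{task}_{modality}"
        core = model.estimator.core_
        arrays = {}
        for i, layer in enumerate(core.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        if hasattr(model.estimator, "classes_"):
            arrays["classes"] = model.estimator.classes_
        if hasattr(model.estimator, "n_outputs_"):
            arrays["n_outputs"] = np.array([model.estimator.n_outputs_])
        np.savez(stem.with_suffix(".npz"), **arrays)
        meta = {
            "task": task,
            "modality": modality,
            "seed": model.seed,
            "loss_curve": model.loss_curve,
            "spec": {
                k: getattr(model.spec, k)
                for k in (
                    "task",
                    "n_outputs",
                    "loss",
                    "conv1_filters",
                    "conv2_filters",
                    "kernel_size",
                    "fc_units",
                    "learning_rate",
                    "batch_size",
                    "n_epochs",
                    "momentum",
                )
            },
        }
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_models(out_dir) -> Dict[Tuple[str, str], TrainedModel]:
    from .networks import _CNNCore  # rebuilt, then weights overwritten

    out = Path(out_dir)
    models: Dict[Tuple[str, str], TrainedModel] = {}
    for meta_path in sorted(out.glob("*.json")):
        meta = json.loads(meta_path.read_text())
        spec = NetworkSpec(**meta["spec"])
        est = spec.make_estimator(random_state=meta["seed"])
        with np.load(meta_path.with_suffix(".npz")) as d:
            # rebuild the core with the right geometry, then load weights
            est.core_ = _CNNCore(
                16,
                spec.conv1_filters,
                spec.conv2_filters,
                spec.kernel_size,
                spec.fc_units,
                spec.n_outputs if spec.loss != "cross-entropy" else len(d["classes"]),
                np.random.default_rng(0),
            )
            for i, layer in enumerate(est.core_.layers):
                layer.W = d[f"W{i}"].copy()
                layer.b = d[f"b{i}"].copy()
            if "classes" in d:
                est.classes_ = d["classes"].copy()
            if "n_outputs" in d:
                est.n_outputs_ = int(d["n_outputs"][0])
        est.n_features_in_ = 256
        est.loss_curve_ = list(meta["loss_curve"])
        models[(meta["task"], meta["modality"])] = TrainedModel(
            spec=spec,
            estimator=est,
            modality=meta["modality"],
            seed=meta["seed"],
            loss_curve=list(meta["loss_curve"]),
        )
    return models


# ---------------------------------------------------------------------------
# lead-field cache
# ---------------------------------------------------------------------------


def leadfield_cache_key(mesh, electrodes, sigma_bath: float) -> str:
    """Content hash of (mesh nodes/elements, electrode positions, sigma)."""
    import hashlib

    h = hashlib.sha1()
    h.update(np.ascontiguousarray(mesh.node_coords).tobytes())
    h.update(np.ascontiguousarray(mesh.elements).tobytes())
    for name in sorted(electrodes.positions):
        h.update(name.encode())
        h.update(np.ascontiguousarray(electrodes.positions[name]).tobytes())
    h.update(np.float64(sigma_bath).tobytes())
    return h.hexdigest()[:16]


def save_leadfield(cache_dir, key: str, lf) -> None:
    out = Path(cache_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(
        out / f"leadfield_{key}.npz",
        weights=lf.weights,
        electrode_order=np.array(lf.electrode_order),
        electrode_positions=lf.electrode_positions,
        sigma_bath=np.array([lf.sigma_bath]),
        element_volumes=lf.element_volumes,
    )


def load_leadfield(cache_dir, key: str):
    from .leadfield import LeadFieldMatrix

    path = Path(cache_dir) / f"leadfield_{key}.npz"
    if not path.exists():
        return None
    with np.load(path) as d:
        return LeadFieldMatrix(
            weights=d["weights"].copy(),
            electrode_order=tuple(d["electrode_order"]),
            electrode_positions=d["electrode_positions"].copy(),
            sigma_bath=float(d["sigma_bath"][0]),
            element_volumes=d["element_volumes"].copy(),
        )
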