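"""Config-driven end-to-end pipeline and sensitivity sweeps.

The pipeline runs: synthetic geometry -> ventricular coordinates, fibers and
AHA segment models -> electrodes and lead fields -> simulated paced beats ->
16x16 ECG/EGM matrices -> train/test datasets with noise augmentation ->
CNN training -> localization -> a tabular report.  Sensitivity sweeps
(noise level, electrode placement, CIED variants) re-render *test* signals
only and evaluate the frozen models, mirroring a frozen-model testing
protocol; models are never retrained inside a sweep.

Every reported row carries the configuration hash and seed it was produced
from, so any number can be regenerated from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .eikonal import APTemplate, ActivationMap, build_conduction_graph, vm_movie
from .geometry import (
    CIED_ELECTRODES,
    ECG_ELECTRODES,
    ElectrodeParams,
    ElectrodeSet,
    EPParams,
    GeometryParams,
    PacingSite,
    SegmentModel,
    UVCoordinates,
    VentricularMesh,
    assign_fibers,
    build_lv_mesh,
    build_segment_model,
    compute_uvc,
    place_electrodes,
    sample_pacing_sites,
)
from .leadfield import (
    LeadFieldMatrix,
    build_transfer_matrix,
    compute_lead_field,
    with_tip_cloud,
)
from .localization import (
    LocalizationResult,
    cartesian_combine,
    localization_error,
    score_segment_classifier,
    uvc_metric_weights,
    uvc_to_cartesian,
)
from .networks import NetworkSpec, TrainedModel, build_network, train
from .signals import (
    BeatRecord,
    Dataset,
    TraceSet,
    augment,
    build_dataset,
    derive_ecg_channels,
    derive_egm_channels,
    extract_qrs,
    phi_to_wedge,
    resample_16,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "PipelineResult",
    "run_pipeline",
    "simulate_beats",
    "evaluate_models",
    "noise_sweep",
    "electrode_sweep",
    "DEFAULT_NOISE_SNRS",
    "default_electrode_scenarios",
]

ELECTRODE_ORDER = ECG_ELECTRODES + CIED_ELECTRODES
DEFAULT_NOISE_SNRS = (5.0, 10.0, 15.0, 20.0, 30.0)

SCHEMES = ("cartesian17", "cartesian68", "uvc")


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one experiment.  ``seed`` drives every random stream."""

    geometry: GeometryParams = GeometryParams()
    ep: EPParams = EPParams()
    electrodes: ElectrodeParams = ElectrodeParams()
    template: APTemplate = APTemplate()
    n_train: int = 2767
    n_test: int = 1000
    proportions: Tuple[float, float, float] = (0.32, 0.36, 0.32)
    augmentation_k: int = 10
    snr_db: float = 25.0
    test_snr_db: float = 25.0
    qrs_margin_ms: float = 2.0
    schemes: Tuple[str, ...] = SCHEMES
    modalities: Tuple[str, ...] = ("ecg", "egm")
    network_overrides: Mapping[str, Mapping] = field(default_factory=dict)
    seed: int = 0
    out_dir: Optional[str] = None

    def validate(self) -> None:
        self.geometry.validate()
        self.ep.validate()
        self.electrodes.validate()
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")
        if set(self.modalities) - {"ecg", "egm"}:
            raise ValueError("modalities must be subset of {'ecg', 'egm'}")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, Mapping):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        subs = {
            "geometry": GeometryParams,
            "ep": EPParams,
            "electrodes": ElectrodeParams,
            "template": APTemplate,
        }
        kw = {}
        for k, v in d.items():
            if k in subs and isinstance(v, Mapping):
                v = dict(v)
                for tk, tv in v.items():
                    if isinstance(tv, list):
                        v[tk] = tuple(tv)
                kw[k] = subs[k](**v)
            elif isinstance(v, list):
                kw[k] = tuple(v)
            else:
                kw[k] = v
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _child_seed(seed: int, stream: str) -> int:
    h = hashlib.sha1(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


# ---------------------------------------------------------------------------
# beat simulation
# ---------------------------------------------------------------------------


def _ramp_traces(
    transfer: np.ndarray, tau: np.ndarray, template: APTemplate, times: np.ndarray
) -> np.ndarray:
    """Electrode traces for the linear-upstroke template, in closed form.

    With Vm_n(t) = rest + A * clip((t - tau_n)/up, 0, 1), the trace is

        phi_e(t) = rest * S_e + (A/up) * [R_e(t) - R_e(t - up)],
        R_e(t)   = sum_n M_en (t - tau_n)_+,

    evaluated by prefix sums over activation-sorted nodes — algebraically
    identical to ``transfer @ vm_movie(...)`` (valid while the window ends
    before repolarization begins) but O(nodes + times) per electrode.
    """
    order = np.argsort(tau)
    u = tau[order]
    Ms = transfer[:, order]
    P = np.concatenate([np.zeros((Ms.shape[0], 1)), np.cumsum(Ms, axis=1)], axis=1)
    Q = np.concatenate(
        [np.zeros((Ms.shape[0], 1)), np.cumsum(Ms * u[None, :], axis=1)], axis=1
    )

    def ramp_sum(t):
        idx = np.searchsorted(u, t, side="right")
        return t[None, :] * P[:, idx] - Q[:, idx]

    amp = template.amplitude_mv
    rest_term = template.rest_mv * P[:, -1][:, None]
    return rest_term + (amp / template.upstroke_ms) * (
        ramp_sum(times) - ramp_sum(times - template.upstroke_ms)
    )


def simulate_beats(
    mesh: VentricularMesh,
    uvc: UVCoordinates,
    seg_model: SegmentModel,
    sites: Sequence[PacingSite],
    ep: EPParams,
    template: APTemplate,
    transfer: np.ndarray,
    electrode_order: Sequence[str] = ELECTRODE_ORDER,
    margin_ms: float = 2.0,
    graph=None,
    first_id: int = 0,
    taus: Optional[np.ndarray] = None,
) -> List[BeatRecord]:
    """Simulate one paced beat per site and return labelled records with raw
    16x16 ECG and EGM matrices.

    ``transfer`` is the precomputed (n_electrodes x n_nodes) matrix mapping
    nodal Vm to electrode potentials.  ``taus`` optionally supplies
    precomputed activation maps (n_sites x n_nodes)."""
    from scipy.sparse.csgraph import dijkstra

    if graph is None and taus is None:
        graph = build_conduction_graph(mesh, ep)
    records: List[BeatRecord] = []
    nodes = np.array([s.node for s in sites])
    chunk = 128
    for lo in range(0, len(sites), chunk):
        hi = min(lo + chunk, len(sites))
        if taus is not None:
            tau_chunk = taus[lo:hi]
        else:
            tau_chunk = np.atleast_2d(
                dijkstra(graph, directed=False, indices=nodes[lo:hi])
            )
        for k, site in enumerate(sites[lo:hi]):
            act = ActivationMap(tau=tau_chunk[k], source_node=site.node, params=ep)
            # round the simulated duration up to the sampling grid so the
            # QRS window is fully covered
            dur = template.dt_ms * np.ceil(
                (act.max_tau() + template.upstroke_ms + margin_ms) / template.dt_ms
            )
            times = np.arange(0.0, dur + template.dt_ms / 2, template.dt_ms)
            if dur < template.apd_ms + template.upstroke_ms:
                values = _ramp_traces(transfer, act.tau, template, times)
            else:  # window reaches repolarization: fall back to the dense route
                times, vm = vm_movie(act, template, dur)
                values = transfer @ vm
            phi_traces = TraceSet(
                names=tuple(electrode_order), values=values, times=times
            )
            ecg = extract_qrs(derive_ecg_channels(phi_traces), act, template, margin_ms)
            egm = extract_qrs(derive_egm_channels(phi_traces), act, template, margin_ms)
            records.append(
                BeatRecord(
                    beat_id=first_id + lo + k,
                    site=site,
                    seg17=int(seg_model.seg17[site.node]),
                    seg68=int(seg_model.seg68[site.node]),
                    wedge=phi_to_wedge(site.phi),
                    raw_ecg=resample_16(ecg),
                    raw_egm=resample_16(egm),
                )
            )
    return records


# ---------------------------------------------------------------------------
# evaluation of frozen models
# ---------------------------------------------------------------------------


def _noisy_test_matrices(
    records: Sequence[BeatRecord], modality: str, snr_db: Optional[float], seed: int
) -> np.ndarray:
    rng = np.random.default_rng([seed, 0 if modality == "ecg" else 1])
    snr = None if (snr_db is None or np.isinf(snr_db)) else snr_db
    return np.stack(
        [r.matrix(modality, snr_db=snr, rng=rng).values for r in records]
    )


def evaluate_models(
    models: Mapping[Tuple[str, str], TrainedModel],
    test_records: Sequence[BeatRecord],
    mesh: VentricularMesh,
    uvc: UVCoordinates,
    seg_models: Mapping[int, SegmentModel],
    schemes: Sequence[str],
    modalities: Sequence[str],
    snr_db: Optional[float],
    noise_seed: int,
    condition: str = "reference",
) -> Tuple[pd.DataFrame, List[LocalizationResult]]:
    """Score frozen models on (optionally re-noised) test matrices.

    Deterministic: for a fixed (test_records, snr_db, noise_seed) the noise
    realization — and hence every number — is reproducible."""
    weights = uvc_metric_weights(mesh, uvc)
    rows = []
    locs: List[LocalizationResult] = []
    truth_xyz = np.stack([r.site.xyz for r in test_records])
    for modality in modalities:
        X = _noisy_test_matrices(test_records, modality, snr_db, noise_seed)
        Xf = X.reshape(len(X), -1)
        cache: Dict[str, np.ndarray] = {}

        def proba(task: str) -> np.ndarray:
            if task not in cache:
                cache[task] = models[(task, modality)].estimator.predict_proba(Xf)
            return cache[task]

        for scheme in schemes:
            errors = np.empty(len(test_records))
            if scheme in ("cartesian17", "cartesian68"):
                mode = 17 if scheme == "cartesian17" else 68
                seg_task = f"segment{mode}"
                p_seg = proba(seg_task)
                p_ee = proba("epiendo")
                seg_model = seg_models[mode]
                est = models[(seg_task, modality)].estimator
                # align probability columns with segment ids 1..mode
                cols = np.zeros((len(X), mode))
                for j, cls in enumerate(est.classes_):
                    cols[:, int(cls) - 1] = p_seg[:, j]
                ee_est = models[("epiendo", modality)].estimator
                ee = np.zeros((len(X), 2))
                for j, cls in enumerate(ee_est.classes_):
                    ee[:, int(cls)] = p_ee[:, j]
                preds = np.array(
                    [
                        cartesian_combine(cols[i] / cols[i].sum(), ee[i] / ee[i].sum(), seg_model)
                        for i in range(len(X))
                    ]
                )
                truths = np.array(
                    [r.seg17 if mode == 17 else r.seg68 for r in test_records]
                )
                acc, _ = score_segment_classifier(
                    est.classes_[np.argmax(p_seg, axis=1)].astype(int), truths, mode
                )
                pred_uvcs = [None] * len(X)
            elif scheme == "uvc":
                reg = models[("uvc_regression", modality)].estimator
                zr = np.clip(reg.predict(Xf), 0.0, 1.0)
                cls_est = models[("phi_classification", modality)].estimator
                p_phi = proba("phi_classification")
                wedges = cls_est.classes_[np.argmax(p_phi, axis=1)].astype(int)
                from .signals import wedge_to_phi

                preds = np.empty((len(X), 3))
                pred_uvcs = []
                for i in range(len(X)):
                    triple = (zr[i, 0], zr[i, 1], wedge_to_phi(int(wedges[i])))
                    preds[i], _ = uvc_to_cartesian(triple, mesh, uvc, weights)
                    pred_uvcs.append(triple)
                truths = np.array([r.wedge for r in test_records])
                acc, _ = score_segment_classifier(wedges, truths, 68)
            else:
                raise ValueError(f"unknown scheme {scheme!r}")

            errors = np.linalg.norm(preds - truth_xyz, axis=1)
            for i, rec in enumerate(test_records):
                locs.append(
                    LocalizationResult(
                        predicted_xyz=preds[i],
                        truth_xyz=truth_xyz[i],
                        error_mm=float(errors[i]),
                        scheme=scheme,
                        predicted_uvc=pred_uvcs[i],
                        truth_uvc=(rec.site.z, rec.site.rho, rec.site.phi),
                        beat_id=rec.beat_id,
                        modality=modality,
                    )
                )
            rows.append(
                {
                    "condition": condition,
                    "scheme": scheme,
                    "modality": modality,
                    "n": len(test_records),
                    "mean_error_mm": float(errors.mean()),
                    "sd_error_mm": float(errors.std(ddof=1)),
                    "accuracy_pct": acc,
                    "snr_db": snr_db if snr_db is not None else np.inf,
                }
            )
    return pd.DataFrame(rows), locs


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: ExperimentConfig
    mesh: VentricularMesh
    uvc: UVCoordinates
    seg_models: Dict[int, SegmentModel]
    electrodes: ElectrodeSet
    leadfield: LeadFieldMatrix
    transfer: np.ndarray
    dataset: Dataset
    models: Dict[Tuple[str, str], TrainedModel]
    report: pd.DataFrame
    localizations: List[LocalizationResult]
    test_sites: List[PacingSite]


def _required_tasks(schemes: Sequence[str]) -> List[str]:
    tasks: List[str] = []
    if "cartesian17" in schemes:
        tasks += ["segment17", "epiendo"]
    if "cartesian68" in schemes:
        tasks += ["segment68", "epiendo"]
    if "uvc" in schemes:
        tasks += ["uvc_regression", "phi_classification"]
    return sorted(set(tasks))


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: ExperimentConfig) -> PipelineResult:
    """Run the full geometry -> beats -> datasets -> CNNs -> localization
    pipeline and return the per-(scheme, modality) report."""
    config.validate()
    t0 = _stage("geometry")
    try:
        mesh = build_lv_mesh(config.geometry)
        uvc = compute_uvc(mesh)
        mesh = assign_fibers(mesh, uvc)
        seg_models = {
            17: build_segment_model(mesh, uvc, mode=17),
            68: build_segment_model(mesh, uvc, mode=68),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'geometry' failed: {exc}") from exc
    logger.info(
        "mesh: %d nodes, %d tets (%.1fs)", mesh.n_nodes, mesh.n_elements, time.time() - t0
    )

    t0 = _stage("lead field")
    try:
        electrodes = place_electrodes(config.electrodes, config.geometry)
        lf = compute_lead_field(mesh, electrodes, config.ep.sigma_bath, ELECTRODE_ORDER)
        transfer = build_transfer_matrix(lf, mesh, config.ep.sigma_intra)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'lead field' failed: {exc}") from exc

    t0 = _stage("beat simulation")
    try:
        n_beats = config.n_train + config.n_test
        sites = sample_pacing_sites(
            mesh,
            uvc,
            n_beats,
            config.proportions,
            seed=_child_seed(config.seed, "sites"),
        )
        beats = simulate_beats(
            mesh,
            uvc,
            seg_models[17],
            sites,
            config.ep,
            config.template,
            transfer,
            margin_ms=config.qrs_margin_ms,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'beat simulation' failed: {exc}") from exc
    logger.info("simulated %d beats (%.1fs)", len(beats), time.time() - t0)

    t0 = _stage("dataset")
    try:
        dataset = build_dataset(
            beats, config.n_train, config.n_test, seed=_child_seed(config.seed, "split")
        )
        if config.augmentation_k > 1:
            dataset = augment(
                dataset,
                config.augmentation_k,
                config.snr_db,
                np.random.default_rng(_child_seed(config.seed, "augment")),
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'dataset' failed: {exc}") from exc

    t0 = _stage("training")
    try:
        models: Dict[Tuple[str, str], TrainedModel] = {}
        for task in _required_tasks(config.schemes):
            spec = build_network(task, **dict(config.network_overrides.get(task, {})))
            for modality in config.modalities:
                seed = _child_seed(config.seed, f"train:{task}:{modality}")
                models[(task, modality)] = train(spec, dataset, modality, seed=seed)
                logger.info(
                    "trained %s/%s (final loss %.4f)",
                    task,
                    modality,
                    models[(task, modality)].loss_curve[-1],
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'training' failed: {exc}") from exc
    logger.info("training done (%.1fs)", time.time() - t0)

    t0 = _stage("localization")
    try:
        report, locs = evaluate_models(
            models,
            dataset.test,
            mesh,
            uvc,
            seg_models,
            config.schemes,
            config.modalities,
            config.test_snr_db,
            noise_seed=_child_seed(config.seed, "test-noise"),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'localization' failed: {exc}") from exc
    report["config_hash"] = config.config_hash
    report["seed"] = config.seed
    logger.info("evaluation done (%.1fs)\n%s", time.time() - t0, report.to_string())

    result = PipelineResult(
        config=config,
        mesh=mesh,
        uvc=uvc,
        seg_models=seg_models,
        electrodes=electrodes,
        leadfield=lf,
        transfer=transfer,
        dataset=dataset,
        models=models,
        report=report,
        localizations=locs,
        test_sites=[r.site for r in dataset.test],
    )
    if config.out_dir:
        _persist(result)
    return result


def _persist(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report.csv", index=False)
    result.electrodes.to_table().to_csv(out / "electrodes.csv", index=False)
    result.config.to_yaml(out / "config.yaml")
    rows = [
        {
            "beat_id": l.beat_id,
            "scheme": l.scheme,
            "modality": l.modality,
            "pred_x": l.predicted_xyz[0],
            "pred_y": l.predicted_xyz[1],
            "pred_z": l.predicted_xyz[2],
            "truth_x": l.truth_xyz[0],
            "truth_y": l.truth_xyz[1],
            "truth_z": l.truth_xyz[2],
            "error_mm": l.error_mm,
        }
        for l in result.localizations
    ]
    pd.DataFrame(rows).to_csv(out / "localizations.csv", index=False)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def noise_sweep(
    result: PipelineResult, snr_list: Sequence[float] = DEFAULT_NOISE_SNRS
) -> pd.DataFrame:
    """Re-noise the retained test matrices at each SNR and evaluate the
    frozen models (no retraining)."""
    if not result.models:
        raise ValueError("no trained models in pipeline result")
    frames = []
    for snr in snr_list:
        df, _ = evaluate_models(
            result.models,
            result.dataset.test,
            result.mesh,
            result.uvc,
            result.seg_models,
            result.config.schemes,
            result.config.modalities,
            snr,
            noise_seed=_child_seed(result.config.seed, f"noise-sweep:{snr}"),
            condition=f"snr_{snr:g}dB",
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["config_hash"] = result.config.config_hash
    out["seed"] = result.config.seed
    return out


def default_electrode_scenarios(shift_mm: float = 50.0) -> Dict[str, dict]:
    """The stock placement-sensitivity scenarios: identity, +/- axis shifts
    of all ECG electrodes, a ~2x shift spread, LV-lead spacing variants, the
    2-mm tip-cloud averaging and a septal RV-coil reposition."""
    s = shift_mm
    scen: Dict[str, dict] = {"identity": {"kind": "identity"}}
    for axis, name in ((0, "x"), (1, "y"), (2, "z")):
        for sign, tag in ((1.0, "plus"), (-1.0, "minus")):
            v = [0.0, 0.0, 0.0]
            v[axis] = sign * s
            scen[f"ecg_shift_{tag}_{name}"] = {"kind": "ecg_shift", "vector_mm": v}
    scen["ecg_spread"] = {"kind": "ecg_shift", "vector_mm": [s, s, -s]}
    for spacing in (5.0, 15.0):
        scen[f"lv_spacing_{spacing:g}mm"] = {"kind": "lv_spacing", "spacing_mm": spacing}
    scen["tip_cloud_2mm"] = {"kind": "tip_cloud", "radius_mm": 2.0}
    scen["rv_septal_coil"] = {"kind": "rv_septal"}
    return scen


def _apply_scenario(
    result: PipelineResult, scenario: Mapping
) -> Tuple[ElectrodeSet, Optional[float]]:
    es = result.electrodes
    kind = scenario["kind"]
    if kind == "identity":
        return es, None
    if kind == "ecg_shift":
        return es.displaced(scenario["vector_mm"]), None
    if kind == "lv_spacing":
        return es.with_lv_spacing(scenario["spacing_mm"]), None
    if kind == "tip_cloud":
        return es, float(scenario["radius_mm"])
    if kind == "rv_septal":
        geom = result.config.geometry
        r = geom.epi_radius + result.config.electrodes.rv_offset
        return es.with_position("RVcoil", [r, 0.0, 0.55 * geom.epi_length]), None
    raise ValueError(f"unknown scenario kind {kind!r}")


def electrode_sweep(
    result: PipelineResult, scenarios: Optional[Mapping[str, Mapping]] = None
) -> pd.DataFrame:
    """Evaluate the frozen models under perturbed electrode configurations.

    For every scenario the lead field is recomputed, the retained test beats
    re-rendered through the new transfer matrix (activation maps are reused
    — they do not depend on electrodes) and the models evaluated.  The
    identity scenario reproduces the reference rows exactly."""
    if not result.models:
        raise ValueError("no trained models in pipeline result")
    if scenarios is None:
        scenarios = default_electrode_scenarios()

    cfg = result.config
    mesh, uvc = result.mesh, result.uvc
    graph = build_conduction_graph(mesh, cfg.ep)
    frames = []
    for name, scenario in scenarios.items():
        es, cloud_radius = _apply_scenario(result, scenario)
        lf = compute_lead_field(mesh, es, cfg.ep.sigma_bath, ELECTRODE_ORDER)
        if cloud_radius is not None:
            tips = [n for n in ELECTRODE_ORDER if "tip" in n.lower() or n == "RVring"]
            lf = with_tip_cloud(mesh, lf, tips, cloud_radius)
        transfer = build_transfer_matrix(lf, mesh, cfg.ep.sigma_intra)
        records = simulate_beats(
            mesh,
            uvc,
            result.seg_models[17],
            result.test_sites,
            cfg.ep,
            cfg.template,
            transfer,
            margin_ms=cfg.qrs_margin_ms,
            graph=graph,
            first_id=min(r.beat_id for r in result.dataset.test),
        )
        # keep original beat ids so noise streams match the reference run
        for rec, orig in zip(records, result.dataset.test):
            rec.beat_id = orig.beat_id
        df, _ = evaluate_models(
            result.models,
            records,
            mesh,
            uvc,
            result.seg_models,
            cfg.schemes,
            cfg.modalities,
            cfg.test_snr_db,
            noise_seed=_child_seed(cfg.seed, "test-noise"),
            condition=name,
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["config_hash"] = cfg.config_hash
    out["seed"] = cfg.seed
    return out
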