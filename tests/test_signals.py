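"""Signal processing: lead identities, channel enumeration, QRS windowing,
resampling, SNR-controlled noise, wedges, and dataset hygiene."""

import numpy as np
import pytest

from pvcloc.eikonal import APTemplate, ActivationMap, solve_activation
from pvcloc.geometry import EPParams, PacingSite
from pvcloc.signals import (
    ECG_CHANNELS,
    EGM_CHANNELS,
    N_WEDGES,
    WEDGE_WIDTH,
    BeatRecord,
    Dataset,
    TraceSet,
    add_noise,
    augment,
    build_dataset,
    derive_ecg_channels,
    derive_egm_channels,
    extract_qrs,
    normalize_matrix,
    phi_to_wedge,
    resample_16,
    wedge_to_phi,
)

from conftest import make_rod_mesh, with_fibers

ECG_NAMES = ("V1", "V2", "V3", "V4", "V5", "V6", "RA", "LA", "LL")
EGM_NAMES = (
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


def random_traces(names, n_t=40, seed=0):
    rng = np.random.default_rng(seed)
    return TraceSet(
        names=tuple(names),
        values=rng.standard_normal((len(names), n_t)),
        times=np.arange(n_t) * 0.5,
    )


def constant_traces(names, values, n_t=8):
    vals = np.array([[values[n]] * n_t for n in names], dtype=float)
    return TraceSet(names=tuple(names), values=vals, times=np.arange(n_t) * 1.0)


class TestECGDerivation:
    def test_einthoven_identity(self):
        ecg = derive_ecg_channels(random_traces(ECG_NAMES))
        I, II, III = ecg.get("I"), ecg.get("II"), ecg.get("III")
        assert np.allclose(I + III - II, 0.0, atol=1e-12)

    def test_goldberger_identity(self):
        ecg = derive_ecg_channels(random_traces(ECG_NAMES, seed=4))
        s = ecg.get("aVR") + ecg.get("aVL") + ecg.get("aVF")
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_documented_arithmetic_on_constants(self):
        vals = {n: 0.0 for n in ECG_NAMES}
        vals.update({"RA": 1.0, "LA": 3.0, "LL": 5.0})
        ecg = derive_ecg_channels(constant_traces(ECG_NAMES, vals))
        assert np.allclose(ecg.get("I"), 2.0)
        assert np.allclose(ecg.get("II"), 4.0)
        assert np.allclose(ecg.get("III"), 2.0)
        assert np.allclose(ecg.get("LL-RA-LA"), 1.0)
        assert np.allclose(ecg.get("(RA+LA+LL)/2"), 4.5)

    def test_channel_count_and_order(self):
        ecg = derive_ecg_channels(random_traces(ECG_NAMES))
        assert ecg.names == ECG_CHANNELS
        assert len(ecg.names) == 16

    def test_missing_electrode_named_in_error(self):
        bad = random_traces([n for n in ECG_NAMES if n != "LA"])
        with pytest.raises(ValueError, match="LA"):
            derive_ecg_channels(bad)


class TestEGMDerivation:
    def test_sixteen_channels(self):
        egm = derive_egm_channels(random_traces(EGM_NAMES))
        assert len(egm.names) == 16
        assert egm.names == EGM_CHANNELS

    def test_equal_potentials_give_zero_channels(self):
        egm = derive_egm_channels(constant_traces(EGM_NAMES, {n: 3.7 for n in EGM_NAMES}))
        assert np.allclose(egm.values, 0.0)

    def test_can_svc_antisymmetry(self):
        tr = random_traces(EGM_NAMES, seed=9)
        swapped_vals = tr.values.copy()
        i_can, i_svc = tr.names.index("CAN"), tr.names.index("SVC")
        swapped_vals[[i_can, i_svc]] = swapped_vals[[i_svc, i_can]]
        swapped = TraceSet(names=tr.names, values=swapped_vals, times=tr.times)
        a = derive_egm_channels(tr).get("CAN-SVC")
        b = derive_egm_channels(swapped).get("CAN-SVC")
        assert np.allclose(a, -b)


@pytest.fixture(scope="module")
def rod_activation(ep):
    rod = with_fibers(make_rod_mesh(10, 1.0), [1, 0, 0])
    return solve_activation(rod, 0, ep)


class TestQRSWindow:
    def test_window_length_arithmetic(self):
        act = ActivationMap(tau=np.array([0.0, 40.0, 80.0]), source_node=0, params=EPParams())
        tmpl = APTemplate(upstroke_ms=1.0)
        times = np.arange(0.0, 120.0, 0.5)
        tr = TraceSet(names=("a",), values=np.zeros((1, len(times))), times=times)
        out = extract_qrs(tr, act, tmpl, margin_ms=0.0)
        assert np.isclose(out.times[-1], 81.0)

    def test_same_window_for_all_channels(self, rod_activation):
        times = np.arange(0.0, 60.0, 0.5)
        tr = TraceSet(
            names=tuple("abcd"), values=np.random.default_rng(0).standard_normal((4, len(times))), times=times
        )
        out = extract_qrs(tr, rod_activation, APTemplate(), 2.0)
        assert out.values.shape[0] == 4  # one shared time axis by construction

    def test_window_exceeding_duration_rejected(self, rod_activation):
        times = np.arange(0.0, 5.0, 0.5)
        tr = TraceSet(names=("a",), values=np.zeros((1, len(times))), times=times)
        with pytest.raises(ValueError):
            extract_qrs(tr, rod_activation, APTemplate(), 2.0)

    def test_sources_quiescent_after_window(self, mesh, uvc, electrodes, ep):
        # energy outside the QRS window is negligible: after full activation
        # every node sits on the plateau, so gradients (and signals) vanish
        from pvcloc.experiments import ELECTRODE_ORDER, _ramp_traces
        from pvcloc.leadfield import build_transfer_matrix, compute_lead_field

        lf = compute_lead_field(mesh, electrodes, ep.sigma_bath, ELECTRODE_ORDER)
        M = build_transfer_matrix(lf, mesh, ep.sigma_intra)
        act = solve_activation(mesh, 0, ep)
        tmpl = APTemplate()
        end = act.max_tau() + tmpl.upstroke_ms
        times = np.arange(0.0, end + 50.0, tmpl.dt_ms)
        phi = _ramp_traces(M, act.tau, tmpl, times)
        inside = times <= end + 2.0
        # signals are potential differences of rows; use a representative pair
        sig = phi[0] - phi[1]
        tail_energy = np.sum(sig[~inside] ** 2)
        total = np.sum(sig**2)
        assert tail_energy / total < 1e-9


class TestResample:
    def test_constant_trace(self):
        tr = TraceSet(names=("a",), values=np.full((1, 30), 2.5), times=np.arange(30.0))
        out = resample_16(tr)
        assert out.shape == (1, 16)
        assert np.allclose(out, 2.5)

    def test_linear_ramp_endpoints_preserved(self):
        times = np.arange(33.0)
        tr = TraceSet(names=("a",), values=times[None, :] * 0.7, times=times)
        out = resample_16(tr)
        assert np.isclose(out[0, 0], 0.0) and np.isclose(out[0, -1], 32.0 * 0.7)

    def test_idempotent_on_uniform_16(self):
        times = np.linspace(0.0, 10.0, 16)
        vals = np.random.default_rng(1).standard_normal((3, 16))
        tr = TraceSet(names=("a", "b", "c"), values=vals, times=times)
        assert np.allclose(resample_16(tr), vals)

    def test_too_short_trace_rejected(self):
        tr = TraceSet(names=("a",), values=np.zeros((1, 1)), times=np.zeros(1))
        with pytest.raises(ValueError):
            resample_16(tr)


class TestNoise:
    def test_infinite_snr_is_identity(self):
        x = np.random.default_rng(0).standard_normal((4, 100))
        assert np.array_equal(add_noise(x, np.inf, np.random.default_rng(1)), x)

    def test_empirical_snr_within_half_db(self):
        t = np.linspace(0, 1000, 200_000)
        x = np.sin(2 * np.pi * 0.013 * t)[None, :]
        noisy = add_noise(x, 25.0, np.random.default_rng(42))
        noise = noisy - x
        snr = 10 * np.log10(np.mean(x**2) / np.mean(noise**2))
        assert abs(snr - 25.0) < 0.5

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(0).standard_normal((2, 50))
        a = add_noise(x, 10.0, np.random.default_rng(7))
        b = add_noise(x, 10.0, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_normalization_max_abs_one(self):
        x = np.random.default_rng(3).standard_normal((16, 16)) * 13.0
        vals, scale = normalize_matrix(x)
        assert np.isclose(np.abs(vals).max(), 1.0)
        assert np.allclose(vals * scale, x)


class TestWedges:
    def test_width_to_two_decimals(self):
        assert round(WEDGE_WIDTH, 2) == 0.09

    def test_boundary_conventions(self):
        assert phi_to_wedge(-np.pi) == 1
        assert phi_to_wedge(np.pi) == N_WEDGES

    def test_round_trip_all_classes(self):
        for k in range(1, N_WEDGES + 1):
            assert phi_to_wedge(wedge_to_phi(k)) == k

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            phi_to_wedge(4.0)
        with pytest.raises(ValueError):
            wedge_to_phi(0)


def _dummy_record(i, wall="mid", rng=None):
    rng = rng or np.random.default_rng(i)
    site = PacingSite(
        node=i, xyz=np.zeros(3), z=0.5, rho=0.5, phi=0.1, wall_class=wall
    )
    return BeatRecord(
        beat_id=i,
        site=site,
        seg17=1,
        seg68=1,
        wedge=phi_to_wedge(0.1),
        raw_ecg=rng.standard_normal((16, 16)),
        raw_egm=rng.standard_normal((16, 16)),
    )


class TestDataset:
    def _beats(self, n):
        walls = ["endo", "mid", "epi"]
        return [_dummy_record(i, walls[i % 3]) for i in range(n)]

    def test_split_sizes_and_disjointness(self):
        ds = build_dataset(self._beats(60), 40, 20, seed=0)
        assert len(ds.train) == 40 and len(ds.test) == 20
        assert not ({r.beat_id for r in ds.train} & {r.beat_id for r in ds.test})

    def test_epiendo_view_excludes_midwall(self):
        ds = build_dataset(self._beats(60), 40, 20, seed=0)
        assert all(r.site.wall_class != "mid" for r in ds.epiendo_train())

    def test_same_seed_same_split(self):
        beats = self._beats(50)
        a = build_dataset(beats, 30, 20, seed=5)
        b = build_dataset(beats, 30, 20, seed=5)
        assert [r.beat_id for r in a.train] == [r.beat_id for r in b.train]

    def test_insufficient_beats_rejected(self):
        with pytest.raises(ValueError):
            build_dataset(self._beats(10), 8, 5, seed=0)

    def test_augmentation_count_and_label_inheritance(self):
        ds = build_dataset(self._beats(30), 20, 10, seed=1)
        aug = augment(ds, 10, 25.0, np.random.default_rng(0))
        assert len(aug.train) == 200
        assert len(aug.test) == 10
        parents = {r.beat_id: r for r in ds.train}
        for r in aug.train:
            assert r.parent_id in parents
            assert r.seg17 == parents[r.parent_id].seg17
            assert r.site.wall_class == parents[r.parent_id].site.wall_class

    def test_augmented_copies_never_in_test(self):
        ds = build_dataset(self._beats(30), 20, 10, seed=1)
        aug = augment(ds, 3, 25.0, np.random.default_rng(0))
        test_ids = {r.beat_id for r in aug.test}
        assert all(r.parent_id not in test_ids for r in aug.train)

    def test_k1_infinite_snr_preserves_matrices(self):
        ds = build_dataset(self._beats(12), 8, 4, seed=2)
        aug = augment(ds, 1, np.inf, np.random.default_rng(0))
        for orig, copy in zip(ds.train, aug.train):
            assert np.array_equal(orig.raw_ecg, copy.raw_ecg)

    def test_matrix_views_normalized(self):
        ds = build_dataset(self._beats(12), 8, 4, seed=2)
        X = ds.matrices("train", "ecg")
        assert X.shape == (8, 16, 16)
        assert np.allclose(np.abs(X).max(axis=(1, 2)), 1.0)


class TestPersistenceRoundTrip:
    def test_dataset_round_trips_bit_exactly(self, tmp_path):
        from pvcloc.persist import load_dataset, save_dataset

        ds = build_dataset([_dummy_record(i, ["endo", "mid", "epi"][i % 3]) for i in range(20)], 12, 6, seed=3)
        ds = augment(ds, 2, 25.0, np.random.default_rng(1))
        path = tmp_path / "ds.npz"
        save_dataset(path, ds)
        back = load_dataset(path)
        assert len(back.train) == len(ds.train)
        for a, b in zip(ds.train + ds.test, back.train + back.test):
            assert a.beat_id == b.beat_id and a.parent_id == b.parent_id
            assert np.array_equal(a.raw_ecg, b.raw_ecg)
            assert np.array_equal(a.raw_egm, b.raw_egm)
            assert a.site.wall_class == b.site.wall_class
            assert (a.seg17, a.seg68, a.wedge) == (b.seg17, b.seg68, b.wedge)
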