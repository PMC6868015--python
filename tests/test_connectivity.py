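"""STTC and CorSE: oracle equivalence, invariances, null behaviour."""

import numpy as np
import pytest

from meanet.connectivity import (
    average_corse,
    connectivity_map,
    corse,
    corse_matrix,
    spectral_entropy_series,
    sttc,
    sttc_matrix,
)
from meanet.io import CorseConfig, RawRecording, SpikeTable
from meanet.simulate import WaveformModel, preset, simulate_trains, synthesize_raw

FS = 12500.0


from oracles import sttc_oracle


class TestSttc:
    def test_self_comparison_is_one(self, rng):
        a = np.sort(rng.uniform(0, 100, 50))
        assert sttc(a, a.copy(), 0.05, 600.0) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_case(self):
        # T_A = T_B = 0.1, P_A = P_B = 0 → ½(−0.1/1 + −0.1/1) = −0.1
        assert sttc(np.array([5.0]), np.array([8.0]), 0.5, 10.0) == pytest.approx(-0.1)

    def test_oracle_equivalence_500_pairs(self, rng):
        for _ in range(500):
            na, nb = rng.integers(1, 31, 2)
            a = np.sort(rng.uniform(0, 20, na))
            b = np.sort(rng.uniform(0, 20, nb))
            dt = float(rng.uniform(0.01, 1.0))
            got = sttc(a, b, dt, 20.0)
            want = sttc_oracle(a, b, dt, 20.0)
            assert got == pytest.approx(want, abs=1e-12)
            assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12

    def test_symmetry(self, rng):
        a = np.sort(rng.uniform(0, 50, 40))
        b = np.sort(rng.uniform(0, 50, 25))
        assert sttc(a, b, 0.05, 50.0) == sttc(b, a, 0.05, 50.0)

    def test_joint_translation_invariance(self, rng):
        # shifting both trains inside a window of the same length leaves
        # tiling fractions and coincidence proportions unchanged
        a = np.sort(rng.uniform(1, 8, 20))
        b = np.sort(rng.uniform(1, 8, 20))
        v1 = sttc(a, b, 0.05, 10.0)
        v2 = sttc(a + 0.7, b + 0.7, 0.05, 10.0)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_empty_train_undefined(self):
        assert sttc(np.array([]), np.array([1.0]), 0.05, 10.0) is None

    def test_null_independent_poisson_near_zero(self, rng):
        vals = []
        for _ in range(200):
            a = np.sort(rng.uniform(0, 600, 1200))
            b = np.sort(rng.uniform(0, 600, 1200))
            vals.append(sttc(a, b, 0.05, 600.0))
        assert abs(np.mean(vals)) < 0.02


class TestSttcMatrix:
    def test_identical_trains_all_one(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 60, 100))
        table = SpikeTable(
            duration=60.0, spikes={("W1", f"E{i}"): t.copy() for i in range(4)}
        )
        mat, summary, ids = sttc_matrix(table, "W1")
        off = mat[np.triu_indices(4, 1)]
        np.testing.assert_allclose(off, 1.0, atol=1e-12)
        assert summary == pytest.approx(1.0)

    def test_symmetric(self, rng):
        table = SpikeTable(
            duration=60.0,
            spikes={("W1", f"E{i}"): np.sort(rng.uniform(0, 60, 80)) for i in range(5)},
        )
        mat, _, _ = sttc_matrix(table, "W1")
        np.testing.assert_array_equal(mat, mat.T)

    def test_summary_decreases_with_jitter(self):
        summaries = []
        for jitter in (0.0, 0.01, 0.05, 0.2):
            p = preset("rat_peak")
            p.duration_s = 120.0
            p.n_electrodes = 6
            p.jitter_s = jitter
            truth = simulate_trains(p, seed=17)
            _, s, _ = sttc_matrix(truth.true_spikes, "W1")
            summaries.append(s)
        assert all(a >= b for a, b in zip(summaries, summaries[1:]))

    def test_phenotype_direction(self):
        vals = {}
        for kind in ("hPSC_peak", "rat_peak"):
            p = preset(kind)
            p.duration_s = 120.0
            p.n_electrodes = 8
            truth = simulate_trains(p, seed=23)
            _, vals[kind], _ = sttc_matrix(truth.true_spikes, "W1")
        assert vals["rat_peak"] > vals["hPSC_peak"]


class TestSpectralEntropy:
    def test_pure_sine_low_entropy(self):
        t = np.arange(int(30 * FS)) / FS
        se = spectral_entropy_series(np.sin(2 * np.pi * 1000 * t), FS)
        assert se.mean() < 0.3

    def test_white_noise_high_entropy(self, rng):
        se = spectral_entropy_series(rng.normal(0, 1, int(30 * FS)), FS)
        assert se.mean() > 0.9

    def test_zero_trace_entropy_one_by_convention(self):
        with pytest.warns(UserWarning):
            se = spectral_entropy_series(np.zeros(int(12 * FS)), FS)
        np.testing.assert_allclose(se, 1.0)

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError):
            spectral_entropy_series(np.zeros(1000), FS, window_s=0.001)


class TestCorse:
    def test_self_correlation_is_one(self, rng):
        a = rng.normal(0, 1, int(20 * FS))
        assert corse(a, a.copy(), FS) == pytest.approx(1.0)

    def test_amplitude_scaling_invariance(self, rng):
        a = rng.normal(0, 1, int(20 * FS))
        b = rng.normal(0, 1, int(20 * FS))
        v1 = corse(a, b, FS)
        v2 = corse(a * 3.7, b * 0.01, FS)
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_independent_noise_null(self):
        vals = []
        for s in range(50):
            r = np.random.default_rng(400 + s)
            x = r.normal(0, 1, int(120 * FS))
            y = r.normal(0, 1, int(120 * FS))
            vals.append(corse(x, y, FS))
        assert np.mean(vals) < 0.3

    def test_shared_burst_envelope_strongly_connected(self):
        p = preset("hPSC_peak")
        p.duration_s = 60.0
        p.n_electrodes = 2
        truth = simulate_trains(p, seed=9)
        raw = synthesize_raw(truth, WaveformModel(amplitude_uv=60.0), fs=FS)
        assert corse(raw.traces[0], raw.traces[1], FS) > 0.7

    def test_constant_series_undefined(self):
        with pytest.warns(UserWarning):
            v = corse(np.zeros(int(12 * FS)), np.zeros(int(12 * FS)), FS)
        assert v is None


class TestMapsAndAverages:
    def test_map_threshold_and_ordering(self):
        mat = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.75], [0.2, 0.75, 1.0]])
        edges = connectivity_map(mat, ["E2", "E1", "E3"], 0.7)
        assert edges == [("E1", "E2", 0.8), ("E1", "E3", 0.75)]
        assert connectivity_map(mat, ["a", "b", "c"], 1.0) == []
        assert len(connectivity_map(mat, ["a", "b", "c"], 0.0)) == 3

    def test_average_corse(self):
        mat = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        assert average_corse(mat) == pytest.approx(0.4)
        assert average_corse(np.array([[1.0]])) is None

    def test_identical_channels_average_one(self, rng):
        x = rng.normal(0, 1, int(15 * FS))
        rec = RawRecording("W1", ["E1", "E2"], np.vstack([x, x]), FS)
        mat, _ = corse_matrix(rec, CorseConfig(bandpass=False))
        assert average_corse(mat) == pytest.approx(1.0)
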