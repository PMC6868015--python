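"""Consensus spike detection: filter, noise SD, threshold, SWTTEO, consensus."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from meanet.detection import (
    active_electrodes,
    bandpass_filter,
    consensus_spikes,
    detect_spikes,
    estimate_noise_sd,
    swtteo_energy,
    swtteo_select,
    threshold_detect,
)
from meanet.io import SpikeTable
from meanet.simulate import spike_template

FS = 12500.0


class TestBandpass:
    def test_passband_unity(self):
        t = np.arange(int(2 * FS)) / FS
        out = bandpass_filter(np.sin(2 * np.pi * 1000 * t), FS)
        mid = out[int(0.5 * FS) : int(1.5 * FS)]
        assert 0.95 <= np.abs(mid).max() <= 1.05

    def test_stopband_attenuation(self):
        t = np.arange(int(2 * FS)) / FS
        out = bandpass_filter(np.sin(2 * np.pi * 10 * t), FS)
        assert np.abs(out[int(0.5 * FS) : int(1.5 * FS)]).max() < 0.05

    def test_zero_in_zero_out_and_length(self):
        out = bandpass_filter(np.zeros(10000), FS)
        assert out.shape == (10000,)
        np.testing.assert_array_equal(out, 0.0)

    def test_bad_band_raises(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(10000), FS, f_lo=200, f_hi=7000)


class TestNoiseSd:
    def test_consistent_on_gaussian(self, rng):
        x = rng.normal(0, 1, 125000)
        assert 0.97 <= estimate_noise_sd(x) <= 1.03

    def test_constant_trace_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert estimate_noise_sd(np.zeros(2000)) == 0.0

    def test_robust_to_sparse_spikes_where_plain_sd_is_not(self, rng):
        x = rng.normal(0, 1, 125000)
        idx = rng.choice(x.size, size=x.size // 100, replace=False)
        x[idx] = 20.0
        assert 0.97 <= estimate_noise_sd(x) <= 1.05
        assert x.std() > 2.0


class TestThresholdDetect:
    def test_single_negative_sample(self):
        x = np.zeros(20000)
        x[1000] = -10.0
        times = threshold_detect(x, FS, sigma_hat=1.0, k=4.5)
        np.testing.assert_allclose(times, [1000 / FS])

    def test_dead_time_keeps_larger_extremum(self):
        x = np.zeros(20000)
        x[1000] = -10.0
        x[1006] = -12.0  # 0.48 ms later
        times = threshold_detect(x, FS, 1.0, dead_time_s=1e-3)
        np.testing.assert_allclose(times, [1006 / FS])

    def test_polarity_both_catches_positive(self):
        x = np.zeros(20000)
        x[500] = 9.0
        assert threshold_detect(x, FS, 1.0, polarity="neg").size == 0
        assert threshold_detect(x, FS, 1.0, polarity="both").size == 1

    def test_translation_equivariance(self, rng):
        x = rng.normal(0, 1, 50000)
        x[10000] = -30.0
        x[25000] = -28.0
        sigma = estimate_noise_sd(x)
        t1 = threshold_detect(x, FS, sigma)
        m = 1000
        t2 = threshold_detect(np.r_[np.zeros(m), x], FS, sigma)
        np.testing.assert_allclose(t2, t1 + m / FS, atol=1e-12)


class TestSwtteo:
    def test_zero_trace_zero_energy(self):
        en = swtteo_energy(np.zeros(10000), FS)
        assert en.shape == (10000,)
        np.testing.assert_allclose(en, 0.0, atol=1e-20)

    def test_energy_peak_at_template(self):
        tpl = spike_template(FS)
        half = tpl.size // 2
        x = np.zeros(125000)
        c = 62500
        x[c - half : c + half + 1] = 40 * tpl
        en = swtteo_energy(x, FS)
        # SWT group delay is ~2 samples; must stay well inside 0.25 ms
        assert abs(int(np.argmax(en)) - c) <= int(0.25e-3 * FS)

    def test_spike_dominates_line_noise(self):
        tpl = spike_template(FS)
        half = tpl.size // 2
        t = np.arange(125000) / FS
        sine = 10 * np.sin(2 * np.pi * 50 * t)
        en0 = swtteo_energy(sine, FS)
        x = sine.copy()
        x[62500 - half : 62500 + half + 1] += 40 * tpl
        en1 = swtteo_energy(x, FS)
        assert en1[62480:62520].max() / max(en0.max(), 1e-30) > 5

    def test_select_zero_candidates(self):
        assert swtteo_select(np.random.default_rng(0).random(1000), FS, 0).size == 0

    def test_select_three_isolated_peaks(self):
        en = np.zeros(10000)
        for i in (1000, 4000, 8000):
            en[i] = 5.0
        times = swtteo_select(en, FS, 3)
        np.testing.assert_allclose(times, np.array([1000, 4000, 8000]) / FS)

    def test_level_too_large_raises(self):
        with pytest.raises(ValueError):
            swtteo_energy(np.zeros(10), FS, level=3)


class TestConsensus:
    def test_basic_match(self):
        out = consensus_spikes(np.array([0.1, 0.2]), np.array([0.1001, 0.5]), 1e-3)
        np.testing.assert_allclose(out, [0.1])

    def test_identity(self):
        a = np.array([0.1, 0.5, 0.9])
        np.testing.assert_allclose(consensus_spikes(a, a.copy()), a)

    def test_matches_optimal_bipartite_count(self, rng):
        """Greedy in-order matching attains the optimal match count."""
        for _ in range(20):
            a = np.sort(rng.uniform(0, 10, 50))
            b = np.sort(a + rng.normal(0, 1.5e-3, 50))
            tol = 1e-3
            kept = consensus_spikes(a, b, tol)
            cost = (np.abs(a[:, None] - b[None, :]) <= tol).astype(int)
            ri, ci = linear_sum_assignment(-cost)
            optimal = int(cost[ri, ci].sum())
            assert kept.size == optimal

    def test_tolerance_monotone(self, rng):
        a = np.sort(rng.uniform(0, 10, 100))
        b = np.sort(rng.uniform(0, 10, 100))
        counts = [
            consensus_spikes(a, b, tol).size for tol in (1e-4, 5e-4, 1e-3, 5e-3, 2e-2)
        ]
        assert counts == sorted(counts)

    def test_output_subset_of_threshold_times(self, rng):
        a = np.sort(rng.uniform(0, 10, 60))
        b = np.sort(rng.uniform(0, 10, 60))
        out = consensus_spikes(a, b, 5e-3)
        assert set(out).issubset(set(a))


class TestDetectSpikes:
    def test_zero_noise_recovers_all_inserted_spikes(self, config):
        from meanet.io import SpikeTable
        from meanet.simulate import GroundTruth, NetworkParams, WaveformModel, synthesize_raw

        times = np.linspace(1.0, 9.0, 10)
        table = SpikeTable(duration=10.0, spikes={("W1", "E01"): times})
        p = NetworkParams(n_electrodes=1, duration_s=10.0)
        truth = GroundTruth(table, {}, p, seed=0)
        wf = WaveformModel(noise_sd_uv=0.0, amplitude_cv=0.0)
        rec = synthesize_raw(truth, wf, fs=FS)
        # inject σ̂ via threshold detection on the filtered trace
        filt = bandpass_filter(rec.traces[0], FS)
        det = threshold_detect(filt, FS, sigma_hat=1.0, k=4.5)
        assert det.size == 10
        np.testing.assert_allclose(det, times, atol=1.01 / FS)

    def test_consensus_subset_and_counts(self, hpsc_raw_60s, config):
        res = detect_spikes(hpsc_raw_60s, config)
        pe = res.per_electrode
        assert (pe["n_consensus"] <= pe[["n_threshold", "n_swtteo"]].min(axis=1)).all()
        assert (pe["sigma_hat_uv"] > 0).all()


class TestActiveElectrodes:
    def test_counts_and_percentage(self):
        spikes = {("W1", f"A{i:02d}"): np.linspace(0.1, 599, 120) for i in range(16)}
        spikes.update(
            {("W1", f"B{i:02d}"): np.linspace(0.1, 599, 50) for i in range(48)}
        )
        table = SpikeTable(duration=600.0, spikes=spikes)
        mask, pct = active_electrodes(table)
        assert sum(mask.values()) == 16
        assert pct["W1"] == pytest.approx(25.0)

    def test_exactly_ten_per_minute_is_inactive(self):
        table = SpikeTable(
            duration=600.0, spikes={("W1", "E1"): np.linspace(0.1, 599.9, 100)}
        )
        mask, _ = active_electrodes(table, min_spikes_per_min=10.0)
        assert mask[("W1", "E1")] is False or mask[("W1", "E1")] == False  # noqa: E712

    def test_empty_well_zero_percent(self):
        table = SpikeTable(duration=600.0, spikes={})
        _, pct = active_electrodes(table, electrode_ids={"W1": ["E1", "E2"]})
        assert pct["W1"] == 0.0
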