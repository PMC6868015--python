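"""Generator behaviour: presets, point-process statistics, raw synthesis."""

import numpy as np
import pytest

from meanet.simulate import (
    NetworkParams,
    ResourceError,
    WaveformModel,
    preset,
    simulate_trains,
    spike_template,
    synthesize_raw,
)

FS = 12500.0


class TestPresets:
    def test_hpsc_peak_values(self):
        p = preset("hPSC_peak")
        assert p.burst_rate_per_min == 11.0
        assert p.burst_duration_s == 0.7
        # intra-burst rate chosen so the expected spikes per burst is ≈34
        assert p.expected_spikes_per_burst == pytest.approx(34.0)

    def test_rat_peak_values(self):
        p = preset("rat_peak")
        assert p.burst_rate_per_min == 15.0
        assert p.burst_duration_s == 0.3
        assert p.intra_burst_rate_hz == pytest.approx(100.0)

    def test_unknown_kind_lists_valid(self):
        with pytest.raises(ValueError, match="hPSC_peak"):
            preset("mouse")

    def test_preset_returns_copy(self):
        a = preset("hPSC_peak")
        a.burst_rate_per_min = 1.0
        assert preset("hPSC_peak").burst_rate_per_min == 11.0


class TestSimulateTrains:
    def test_tonic_only_poisson_count(self):
        p = NetworkParams(
            n_electrodes=10, duration_s=600.0, burst_rate_per_min=0.0, tonic_rate_hz=1.0
        )
        truth = simulate_trains(p, seed=7)
        total = truth.true_spikes.n_spikes()
        # Poisson(6000): ±4 SD band
        assert abs(total - 6000) < 4 * np.sqrt(6000)
        assert all(len(v) == 0 for v in truth.true_bursts.values())

    def test_rat_preset_burst_count_in_poisson_band(self):
        truth = simulate_trains(preset("rat_peak"), seed=11)
        counts = [len(v) for v in truth.true_bursts.values()]
        # electrodes share one Poisson(150) network-onset draw, so the
        # across-electrode mean fluctuates with SD ≈ 0.9·√150
        expect = 150 * 0.9
        assert abs(np.mean(counts) - expect) < 4 * 0.9 * np.sqrt(150)

    def test_zero_participation_gives_tonic_only(self):
        p = NetworkParams(n_electrodes=4, duration_s=60.0, participation=0.0, tonic_rate_hz=2.0)
        truth = simulate_trains(p, seed=3)
        assert all(len(v) == 0 for v in truth.true_bursts.values())
        assert truth.true_spikes.n_spikes() > 0

    def test_refractory_enforced(self):
        truth = simulate_trains(preset("rat_peak"), seed=5)
        for t in truth.true_spikes.spikes.values():
            if t.size > 1:
                assert np.diff(t).min() >= 1e-3 - 1e-12

    def test_bit_reproducible(self):
        a = simulate_trains(preset("hPSC_peak"), seed=9)
        b = simulate_trains(preset("hPSC_peak"), seed=9)
        for k in a.true_spikes.spikes:
            np.testing.assert_array_equal(a.true_spikes.spikes[k], b.true_spikes.spikes[k])
        assert a.true_bursts == b.true_bursts

    def test_resource_guard(self):
        p = NetworkParams(n_electrodes=64, duration_s=1e6, tonic_rate_hz=1000.0)
        with pytest.raises(ResourceError):
            simulate_trains(p, seed=0)

    def test_empirical_rates_match_params(self):
        """Burst rate / duration / spikes-per-burst within 3 MC SDs at 600 s."""
        for kind in ("hPSC_peak", "rat_peak"):
            p = preset(kind)
            truth = simulate_trains(p, seed=21)
            n_el = p.n_electrodes
            counts, durs, sizes = [], [], []
            for v in truth.true_bursts.values():
                counts.append(len(v))
                durs += [b[1] - b[0] for b in v]
                sizes += [b[2] for b in v]
            expect_n = p.burst_rate_per_min * 10 * p.participation
            # dominated by the shared Poisson network-onset draw
            se_n = p.participation * np.sqrt(p.burst_rate_per_min * 10)
            assert abs(np.mean(counts) - expect_n) < 3 * se_n
            # generated window duration ≈ nominal − 2/rate (extreme-order gap)
            expect_d = p.burst_duration_s - 2 / p.intra_burst_rate_hz
            assert abs(np.mean(durs) - expect_d) < 3 * np.std(durs) / np.sqrt(len(durs)) + 0.02
            # 1 ms refractory thinning keeps ≈ 1/(1+rτ) of Poisson spikes
            expect_s = p.expected_spikes_per_burst / (1 + p.intra_burst_rate_hz * 1e-3)
            assert abs(np.mean(sizes) - expect_s) < 3 * np.std(sizes) / np.sqrt(
                len(sizes)
            ) + 1.0


class TestSynthesizeRaw:
    def test_single_spike_zero_noise_template_alignment(self):
        from meanet.io import SpikeTable
        from meanet.simulate import GroundTruth

        p = NetworkParams(n_electrodes=1, duration_s=10.0, burst_rate_per_min=0.0, tonic_rate_hz=0.0)
        table = SpikeTable(duration=10.0, spikes={("W1", "E01"): np.array([0.5])})
        truth = GroundTruth(table, {("W1", "E01"): []}, p, seed=0)
        wf = WaveformModel(noise_sd_uv=0.0, amplitude_cv=0.0)
        rec = synthesize_raw(truth, wf, fs=FS)
        assert int(np.argmin(rec.traces[0])) == int(round(0.5 * FS))
        assert rec.traces[0].min() == pytest.approx(-wf.amplitude_uv, rel=1e-6)

    def test_noise_only_sample_sd(self):
        p = NetworkParams(n_electrodes=1, duration_s=60.0, burst_rate_per_min=0.0, tonic_rate_hz=0.0)
        truth = simulate_trains(p, seed=13)
        rec = synthesize_raw(truth, WaveformModel(noise_sd_uv=5.0), fs=FS)
        assert rec.traces[0].std() == pytest.approx(5.0, rel=0.02)

    def test_edge_spike_clipped_with_warning(self):
        from meanet.io import SpikeTable
        from meanet.simulate import GroundTruth

        p = NetworkParams(n_electrodes=1, duration_s=10.0, burst_rate_per_min=0.0, tonic_rate_hz=0.0)
        table = SpikeTable(duration=10.0, spikes={("W1", "E01"): np.array([1e-5])})
        truth = GroundTruth(table, {("W1", "E01"): []}, p, seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            rec = synthesize_raw(truth, WaveformModel(noise_sd_uv=0.0), fs=FS)
        assert rec.traces.shape[1] == int(10 * FS)


def test_template_shape():
    tpl = spike_template(FS)
    assert tpl.size % 2 == 1
    assert tpl.min() == pytest.approx(-1.0)
    assert tpl[tpl.size // 2] == pytest.approx(-1.0)  # negative peak centred
    assert tpl.max() < 0.6  # biphasic with smaller positive rebound
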