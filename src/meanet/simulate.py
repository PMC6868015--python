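"""Synthetic multi-well MEA data with known ground truth.

The generator emulates the phenomenology of cultured cortical networks on
multi-well MEAs: array-wide network bursts riding on tonic background
spiking, rendered (optionally) as raw voltage traces with biphasic spike
waveforms buried in Gaussian plus mains noise.

Generative model
----------------
* Network-burst onsets follow a homogeneous Poisson process at
  ``burst_rate_per_min``.
* In each network burst every electrode participates independently with
  probability ``participation``; a participating electrode's burst onset is
  shifted by ``Normal(0, jitter_s)``.
* Within a burst, spikes are homogeneous Poisson at ``intra_burst_rate_hz``
  over ``burst_duration_s`` (expected spikes per burst is therefore
  ``rate × duration``, analytic by construction).
* Tonic background spiking is an independent Poisson process per electrode
  at ``tonic_rate_hz``.
* All trains are sorted and thinned to a 1 ms refractory interval.

Two presets parameterize the peak-activity phenotypes of human
PSC-derived networks (11 bursts/min, 0.7 s bursts, ≈34 spikes/burst) and
embryonic rat cortical networks (15 bursts/min, 0.3 s bursts, ≈100 Hz
intra-burst spiking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import RawRecording, SpikeTable

__all__ = [
    "NetworkParams",
    "WaveformModel",
    "GroundTruth",
    "ResourceError",
    "PRESETS",
    "preset",
    "simulate_trains",
    "synthesize_raw",
    "spike_template",
    "simulate_plate",
]

REFRACTORY_S = 1e-3   # enforced minimum inter-spike gap in generated trains
MAX_EXPECTED_SPIKES = 10_000_000


class ResourceError(RuntimeError):
    """Requested simulation would be unreasonably large."""


@dataclass
class NetworkParams:
    """Parameters of the point-process network model (rates in Hz unless noted)."""

    n_electrodes: int = 16
    duration_s: float = 600.0
    burst_rate_per_min: float = 11.0
    burst_duration_s: float = 0.7
    intra_burst_rate_hz: float = 34.0 / 0.7
    participation: float = 0.9
    jitter_s: float = 0.02      # SD of per-electrode burst-onset offset
    tonic_rate_hz: float = 0.8
    pct_in_bursts_target: float | None = None  # informative label only

    def __post_init__(self) -> None:
        if min(self.burst_rate_per_min, self.intra_burst_rate_hz, self.tonic_rate_hz) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.participation <= 1:
            raise ValueError("participation must lie in [0, 1]")
        if self.jitter_s < 0:
            raise ValueError("jitter_s must be non-negative")
        if self.burst_rate_per_min > 0 and not (
            self.burst_duration_s < 60.0 / self.burst_rate_per_min
        ):
            raise ValueError("burst_duration_s must be below the mean burst interval")

    @property
    def expected_spikes_per_burst(self) -> float:
        return self.intra_burst_rate_hz * self.burst_duration_s


@dataclass
class WaveformModel:
    """Extracellular waveform and noise model for raw-trace synthesis."""

    template: np.ndarray = field(default=None)  # type: ignore[assignment]
    amplitude_uv: float = 40.0      # mean negative-peak amplitude
    amplitude_cv: float = 0.2       # lognormal coefficient of variation
    noise_sd_uv: float = 5.0
    line_noise_uv: float = 0.0      # 50 Hz sinusoid amplitude
    fs_template: float = 12500.0

    def __post_init__(self) -> None:
        if self.template is None:
            self.template = spike_template(self.fs_template)
        self.template = np.asarray(self.template, dtype=float)
        if self.template.size % 2 != 1:
            raise ValueError("template length must be odd (centre = negative peak)")
        if self.template.size > int(0.002 * self.fs_template) + 1:
            raise ValueError("template support exceeds 2 ms")
        if not self.amplitude_uv > 0 or not self.noise_sd_uv >= 0:
            raise ValueError("amplitude_uv must be > 0 and noise_sd_uv ≥ 0")


@dataclass
class GroundTruth:
    """Generated spikes and the burst windows that produced them."""

    true_spikes: SpikeTable
    #: per (well, electrode): list of (t_start, t_end, n_spikes) burst windows
    true_bursts: dict[tuple[str, str], list[tuple[float, float, int]]]
    params: NetworkParams
    seed: int


# hPSC-derived networks at peak activity fire comparatively long, sparse
# bursts with substantial tonic spiking between them; rat networks fire
# shorter, faster, more fully recruited bursts with little tonic activity.
PRESETS: dict[str, NetworkParams] = {
    "hPSC_peak": NetworkParams(
        n_electrodes=16,
        duration_s=600.0,
        burst_rate_per_min=11.0,
        burst_duration_s=0.7,
        intra_burst_rate_hz=34.0 / 0.7,   # ≈34 spikes per 0.7 s burst
        participation=0.9,
        jitter_s=0.02,
        tonic_rate_hz=0.8,
    ),
    "rat_peak": NetworkParams(
        n_electrodes=16,
        duration_s=600.0,
        burst_rate_per_min=15.0,
        burst_duration_s=0.3,
        intra_burst_rate_hz=100.0,
        participation=0.9,
        jitter_s=0.01,
        tonic_rate_hz=0.3,
    ),
}


def preset(kind: str) -> NetworkParams:
    """Return a fresh copy of a named phenotype parameter set."""
    if kind not in PRESETS:
        raise ValueError(f"unknown preset {kind!r}; valid kinds: {sorted(PRESETS)}")
    return replace(PRESETS[kind])


def _thin_refractory(times: np.ndarray, refractory: float = REFRACTORY_S) -> np.ndarray:
    """Keep a sorted subsequence with gaps ≥ refractory (greedy from the left)."""
    if times.size <= 1:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def simulate_trains(
    params: NetworkParams,
    seed: int,
    well_id: str = "W1",
    min_burst_spikes: int = 5,
) -> GroundTruth:
    """Draw spike trains for one well from the network point-process model.

    ``true_bursts`` records, per electrode, the burst windows in which that
    electrode participated with at least ``min_burst_spikes`` generated
    spikes (windows with fewer spikes are not claimable as bursts by any
    ISI-based detector and are left as background).
    """
    if params.duration_s < 10:
        raise ValueError("duration_s must be at least 10 s")
    exp_total = params.n_electrodes * params.duration_s * params.tonic_rate_hz + (
        params.burst_rate_per_min / 60.0 * params.duration_s
        * params.n_electrodes * params.participation
        * params.expected_spikes_per_burst
    )
    if exp_total > MAX_EXPECTED_SPIKES:
        raise ResourceError(
            f"parameter combination implies ~{exp_total:.2e} spikes (> {MAX_EXPECTED_SPIKES:.0e})"
        )
    rng = np.random.default_rng(seed)
    T = params.duration_s

    # network burst onsets: homogeneous Poisson
    if params.burst_rate_per_min > 0:
        n_bursts = rng.poisson(params.burst_rate_per_min / 60.0 * T)
        onsets = np.sort(rng.uniform(0, T, n_bursts))
    else:
        onsets = np.empty(0)

    electrode_ids = [f"E{i + 1:02d}" for i in range(params.n_electrodes)]
    spikes: dict[tuple[str, str], np.ndarray] = {}
    bursts: dict[tuple[str, str], list[tuple[float, float, int]]] = {}

    for eid in electrode_ids:
        parts: list[np.ndarray] = []
        windows: list[tuple[float, float, int]] = []
        for onset in onsets:
            if rng.random() >= params.participation:
                continue
            start = onset + rng.normal(0.0, params.jitter_s)
            n_in = rng.poisson(params.intra_burst_rate_hz * params.burst_duration_s)
            if n_in == 0:
                continue
            tt = np.sort(start + rng.uniform(0, params.burst_duration_s, n_in))
            tt = _thin_refractory(tt)
            tt = tt[(tt >= 0) & (tt <= T)]
            if tt.size == 0:
                continue
            parts.append(tt)
            if tt.size >= min_burst_spikes:
                windows.append((float(tt[0]), float(tt[-1]), int(tt.size)))
        if params.tonic_rate_hz > 0:
            n_tonic = rng.poisson(params.tonic_rate_hz * T)
            parts.append(np.sort(rng.uniform(0, T, n_tonic)))
        train = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        train = _thin_refractory(train)
        key = (well_id, eid)
        spikes[key] = train
        bursts[key] = sorted(windows)

    table = SpikeTable(duration=T, spikes=spikes)
    return GroundTruth(true_spikes=table, true_bursts=bursts, params=params, seed=seed)


def spike_template(fs: float = 12500.0, width_ms: float = 1.2) -> np.ndarray:
    """Biphasic extracellular spike shape, unit negative peak at the centre.

    A narrow negative Gaussian trough followed by a broader positive
    rebound — the canonical shape of a nearby extracellular unit.
    """
    half = int(round(width_ms / 2 * 1e-3 * fs))
    t = np.arange(-half, half + 1) / fs * 1e3  # ms
    trough = -np.exp(-0.5 * (t / 0.11) ** 2)
    rebound = 0.35 * np.exp(-0.5 * ((t - 0.35) / 0.25) ** 2)
    w = trough + rebound
    return w / np.abs(w.min())


def synthesize_raw(
    truth: GroundTruth,
    wf: WaveformModel,
    fs: float = 12500.0,
    seed: int | None = None,
) -> RawRecording:
    """Render ground-truth trains as raw voltage traces (µV) at ``fs``.

    Each spike inserts the template scaled by a lognormal amplitude
    (mean ``amplitude_uv``, CV ``amplitude_cv``), negative peak aligned to
    the spike sample; white Gaussian noise of ``noise_sd_uv`` and an
    optional 50 Hz sinusoid are added. Spikes whose template would overrun
    the trace edge are clipped with a warning.
    """
    if seed is None:
        seed = truth.seed + 1
    rng = np.random.default_rng(seed)
    params = truth.params
    n_samples = int(round(params.duration_s * fs))
    template = wf.template
    half = template.size // 2

    well_id = truth.true_spikes.wells()[0]
    electrode_ids = sorted(truth.true_spikes.electrodes(well_id))
    traces = np.zeros((len(electrode_ids), n_samples), dtype=float)

    # lognormal with mean m, cv c:  sigma² = ln(1+c²), mu = ln m − sigma²/2
    sigma2 = np.log1p(wf.amplitude_cv**2)
    mu = np.log(wf.amplitude_uv) - sigma2 / 2

    n_clipped = 0
    for row, eid in enumerate(electrode_ids):
        train = truth.true_spikes.train(well_id, eid)
        centers = np.round(train * fs).astype(int)
        amps = rng.lognormal(mu, np.sqrt(sigma2), centers.size)
        for c, a in zip(centers, amps):
            lo, hi = c - half, c + half + 1
            tlo, thi = 0, template.size
            if lo < 0:
                tlo = -lo
                lo = 0
                n_clipped += 1
            if hi > n_samples:
                thi = template.size - (hi - n_samples)
                hi = n_samples
                n_clipped += 1
            if lo >= hi:
                continue
            traces[row, lo:hi] += a * template[tlo:thi]
        if wf.noise_sd_uv > 0:
            traces[row] += rng.normal(0.0, wf.noise_sd_uv, n_samples)
    if wf.line_noise_uv > 0:
        t = np.arange(n_samples) / fs
        traces += wf.line_noise_uv * np.sin(2 * np.pi * 50.0 * t)
    if n_clipped:
        warnings.warn(f"{n_clipped} spike template(s) clipped at trace edges")
    return RawRecording(
        well_id=well_id, electrode_ids=electrode_ids, traces=traces, fs=fs
    )


def simulate_plate(
    kind: str,
    n_wells: int,
    seed: int,
    duration_s: float | None = None,
    n_electrodes: int | None = None,
    well_prefix: str = "W",
) -> list[GroundTruth]:
    """Simulate a plate of wells from one preset, with per-well derived seeds."""
    params = preset(kind)
    if duration_s is not None:
        params = replace(params, duration_s=duration_s)
    if n_electrodes is not None:
        params = replace(params, n_electrodes=n_electrodes)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, n_wells)
    return [
        simulate_trains(params, int(s), well_id=f"{well_prefix}{i + 1:02d}")
        for i, s in enumerate(seeds)
    ]
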