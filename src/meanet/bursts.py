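"""logISI burst detection and burst feature extraction.

The logISI method finds a per-electrode burst-defining inter-spike-interval
threshold (ISITh) from the valley between the intra-burst and inter-burst
peaks of the histogram of log10(ISI). Two modifications are applied on
top of the base algorithm: a burst must contain at least five spikes, and
when ISITh falls below 100 ms, bursts closer than 100 ms are merged (100 ms
is then the minimum time required between bursts).

Burst features (per electrode, then median over the bursting electrodes of
a well): bursts per minute, burst duration, spikes per burst, spike
frequency within bursts, and the percentage of all spikes that fall in
bursts. Non-bursting electrodes are excluded from well aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import BURST_HEADER, LogisiConfig, SpikeTable

__all__ = [
    "Burst",
    "BurstSet",
    "logisi_threshold",
    "detect_bursts",
    "merge_bursts",
    "electrode_bursts",
    "burst_features",
    "well_aggregate",
    "well_burst_features",
    "analyze_bursts",
    "bursts_to_dataframe",
]

#: numerical floor on burst duration (seconds); generated trains carry a
#: 1 ms refractory so real bursts of ≥5 spikes last ≥4 ms — this guard only
#: protects the (n−1)/duration rate against degenerate hand-built input.
DURATION_FLOOR_S = 80e-6


class Burst(NamedTuple):
    t_start: float
    t_end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class BurstSet:
    """Bursts per electrode of one well plus the ISI threshold used.

    ``isi_threshold`` maps electrode id to the computed ISITh in seconds;
    electrodes for which the logISI histogram yields no valid threshold are
    absent from both mappings (deemed non-bursting).
    """

    well_id: str
    bursts: dict[str, list[Burst]] = field(default_factory=dict)
    isi_threshold: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ISI threshold
# ---------------------------------------------------------------------------


def _log_isi_histogram(
    isis: np.ndarray, bins_per_decade: int
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts and bin centres (log10 seconds) of the ISIs."""
    log_isi = np.log10(isis)
    lo = math.floor(log_isi.min() * bins_per_decade) / bins_per_decade
    hi = math.ceil(log_isi.max() * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    n_bins = int(round((hi - lo) * bins_per_decade))
    edges = lo + np.arange(n_bins + 1) / bins_per_decade
    counts, _ = np.histogram(log_isi, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return counts.astype(float), centers


def logisi_threshold(
    train: np.ndarray,
    bins_per_decade: int = 10,
    void_threshold: float = 0.7,
    max_core_isi: float = 0.1,
    min_spikes: int = 5,
) -> float | None:
    """Burst-defining ISI threshold from the log-ISI histogram, or None.

    The histogram of log10(ISI) is lowess-smoothed; if a local peak exists
    at ISI < ``max_core_isi``, the minimum between it and each later peak
    is scored by the void parameter ``1 − h_min/√(h_peak1·h_peak2)``. The
    threshold is the ISI at the deepest (largest-void) qualifying minimum
    (void ≥ ``void_threshold``). None is returned for unimodal histograms
    or trains too short to assess — such electrodes are non-bursting.
    """
    train = np.asarray(train, dtype=float)
    if train.size < max(min_spikes, 3):
        return None
    isis = np.diff(train)
    if isis.size < 2 or np.any(isis <= 0):
        if np.any(isis <= 0):
            raise ValueError("train must be strictly increasing")
        return None
    counts, centers = _log_isi_histogram(isis, bins_per_decade)
    if counts.size < 3:
        return None
    # zero guard bins so that peaks in the first/last occupied bin are visible
    step = 1.0 / bins_per_decade
    counts = np.r_[0.0, counts, 0.0]
    centers = np.r_[centers[0] - step, centers, centers[-1] + step]
    smoothed = lowess(
        counts,
        centers,
        frac=min(1.0, max(0.10, 4.0 / counts.size)),
        it=0,
        return_sorted=False,
    )
    smoothed = np.clip(smoothed, 0.0, None)
    # local maxima of the smoothed histogram; tiny wiggles are not peaks
    prominence = max(1.0, 0.05 * smoothed.max())
    peaks, _ = signal.find_peaks(smoothed, prominence=prominence)
    # flat-topped or edge peaks: include the global max if find_peaks missed it
    if peaks.size == 0 and smoothed.max() > 0:
        peaks = np.array([int(np.argmax(smoothed))])
    intra = [p for p in peaks if 10 ** centers[p] < max_core_isi]
    if not intra:
        return None
    p1 = intra[0]  # first (fastest) intra-burst peak
    best_void = -np.inf
    best_idx: int | None = None
    for p2 in peaks:
        if p2 <= p1:
            continue
        seg = smoothed[p1 : p2 + 1]
        rel = int(np.argmin(seg))
        h_min = seg[rel]
        denom = math.sqrt(smoothed[p1] * smoothed[p2])
        if denom == 0:
            continue
        void = 1.0 - h_min / denom
        if void >= void_threshold and void > best_void:
            best_void = void
            best_idx = p1 + rel
    if best_idx is None:
        return None
    return float(10 ** centers[best_idx])


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------


def _runs_to_bursts(train: np.ndarray, runs: list[tuple[int, int]], min_spikes: int) -> list[Burst]:
    out = []
    for s, e in runs:
        n = e - s + 1
        if n >= min_spikes:
            out.append(Burst(float(train[s]), float(train[e]), n))
    return out


def detect_bursts(
    train: np.ndarray,
    isi_threshold: float,
    min_spikes: int = 5,
    max_core_isi: float = 0.1,
) -> list[Burst]:
    """Group spikes into bursts given an ISI threshold.

    For ISITh ≤ ``max_core_isi``: maximal runs of consecutive ISIs ≤ ISITh.
    For larger ISITh: burst cores are maximal runs with ISI ≤
    ``max_core_isi``, then each core is extended outward while the adjacent
    ISI is ≤ ISITh (overlapping extensions are unioned). Runs with fewer
    than ``min_spikes`` spikes are discarded; burst bounds coincide with
    member spike times.
    """
    if not isi_threshold > 0:
        raise ValueError("isi_threshold must be positive")
    train = np.asarray(train, dtype=float)
    if train.size < min_spikes:
        return []
    isis = np.diff(train)

    def maximal_runs(mask: np.ndarray) -> list[tuple[int, int]]:
        runs = []
        i = 0
        while i < mask.size:
            if mask[i]:
                j = i
                while j + 1 < mask.size and mask[j + 1]:
                    j += 1
                runs.append((i, j + 1))  # spike index range [i, j+1]
                i = j + 1
            i += 1
        return runs

    if isi_threshold <= max_core_isi:
        runs = maximal_runs(isis <= isi_threshold)
        return _runs_to_bursts(train, runs, min_spikes)

    cores = maximal_runs(isis <= max_core_isi)
    extended: list[tuple[int, int]] = []
    for s, e in cores:
        while s > 0 and isis[s - 1] <= isi_threshold:
            s -= 1
        while e < train.size - 1 and isis[e] <= isi_threshold:
            e += 1
        if extended and s <= extended[-1][1]:
            extended[-1] = (extended[-1][0], max(e, extended[-1][1]))
        else:
            extended.append((s, e))
    return _runs_to_bursts(train, extended, min_spikes)


def merge_bursts(
    bursts: list[Burst],
    isi_threshold: float,
    merge_gap: float = 0.1,
) -> list[Burst]:
    """Union consecutive bursts separated by < ``merge_gap``.

    Active only when ISITh < ``merge_gap`` (a fast intra-burst threshold can
    split one physiological burst); ``merge_gap`` then acts as the minimum
    time required between bursts. Idempotent; preserves total spike count.
    """
    if isi_threshold >= merge_gap or len(bursts) <= 1:
        return list(bursts)
    merged = [bursts[0]]
    for b in bursts[1:]:
        prev = merged[-1]
        if b.t_start - prev.t_end < merge_gap:
            merged[-1] = Burst(prev.t_start, b.t_end, prev.n_spikes + b.n_spikes)
        else:
            merged.append(b)
    return merged


def electrode_bursts(
    train: np.ndarray, config: LogisiConfig
) -> tuple[list[Burst], float | None]:
    """Full per-electrode pipeline: ISITh → detection → merge rule."""
    isith = logisi_threshold(
        train,
        config.bins_per_decade,
        config.void_threshold,
        config.max_core_isi_s,
        config.min_spikes,
    )
    if isith is None:
        return [], None
    bursts = detect_bursts(train, isith, config.min_spikes, config.max_core_isi_s)
    bursts = merge_bursts(bursts, isith, config.merge_gap_s)
    return bursts, isith


def analyze_bursts(table: SpikeTable, config: LogisiConfig) -> dict[str, BurstSet]:
    """Detect bursts on every electrode of every well in a spike table."""
    out: dict[str, BurstSet] = {}
    for well in table.wells():
        bset = BurstSet(well_id=well)
        for eid in table.electrodes(well):
            bursts, isith = electrode_bursts(table.train(well, eid), config)
            if isith is not None:
                bset.bursts[eid] = bursts
                bset.isi_threshold[eid] = isith
        out[well] = bset
    return out


def bursts_to_dataframe(burst_sets: dict[str, BurstSet]) -> pd.DataFrame:
    rows = [
        (w, e, b.t_start, b.t_end, b.n_spikes)
        for w, bset in sorted(burst_sets.items())
        for e in sorted(bset.bursts)
        for b in bset.bursts[e]
    ]
    return pd.DataFrame(rows, columns=BURST_HEADER)


# ---------------------------------------------------------------------------
# burst features
# ---------------------------------------------------------------------------


def burst_features(
    bursts: list[Burst],
    train: np.ndarray,
    duration: float,
    isi_based_rate: bool = True,
) -> dict[str, float] | None:
    """Electrode-level burst features; None for a non-bursting electrode.

    ``spike_freq_in_burst_hz`` uses the ISI-based rate (n−1)/duration per
    burst by default (set ``isi_based_rate=False`` for n/duration); per-
    burst quantities are aggregated by the median.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if not bursts:
        return None
    train = np.asarray(train)
    durations = np.array([max(b.duration, DURATION_FLOOR_S) for b in bursts])
    n_spikes = np.array([b.n_spikes for b in bursts], dtype=float)
    numer = n_spikes - 1 if isi_based_rate else n_spikes
    total = train.size
    in_bursts = float(n_spikes.sum())
    return {
        "burst_rate_per_min": 60.0 * len(bursts) / duration,
        "burst_duration_s": float(np.median(durations)),
        "spikes_in_burst": float(np.median(n_spikes)),
        "spike_freq_in_burst_hz": float(np.median(numer / durations)),
        "pct_spikes_in_bursts": 100.0 * in_bursts / total if total else 0.0,
    }


def well_aggregate(
    electrode_features: dict[str, dict[str, float]],
) -> dict[str, float] | None:
    """Median of each feature over the bursting electrodes of a well."""
    if not electrode_features:
        return None
    keys = next(iter(electrode_features.values())).keys()
    return {
        k: float(np.median([f[k] for f in electrode_features.values()]))
        for k in keys
    }


def well_burst_features(
    table: SpikeTable,
    burst_sets: dict[str, BurstSet],
    isi_based_rate: bool = True,
) -> dict[str, dict[str, float]]:
    """Well-level (median over bursting electrodes) burst features."""
    out: dict[str, dict[str, float]] = {}
    for well, bset in burst_sets.items():
        per_el = {}
        for eid, bursts in bset.bursts.items():
            feats = burst_features(
                bursts, table.train(well, eid), table.duration, isi_based_rate
            )
            if feats is not None:
                per_el[eid] = feats
        agg = well_aggregate(per_el)
        if agg is not None:
            out[well] = agg
    return out
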