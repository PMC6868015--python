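"""Pairwise network synchrony (STTC) and functional connectivity (CorSE).

STTC — spike time tiling coefficient. For trains A, B observed on
[0, T] with coincidence half-window Δt:

    T_X = fraction of [0, T] tiled by ∪ₓ [x−Δt, x+Δt]
    P_X = fraction of X's spikes within Δt of any spike of the other train
    STTC = ½ [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ]

The tiling correction makes the coefficient robust to firing-rate
differences; a term with zero denominator is dropped and the remaining
term(s) averaged.

CorSE — correlated spectral entropy. Each channel's trace is reduced to a
time series of per-window spectral entropies (normalized Shannon entropy of
the band-limited power spectrum); the connectivity strength of a channel
pair is the magnitude of the Pearson correlation of their entropy series.
Synchronized bursting modulates the spectral content of both channels
together, so functionally coupled channels correlate even when their
amplitudes differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import CONN_HEADER, CorseConfig, RawRecording, SpikeTable, SttcConfig
from .detection import bandpass_filter

__all__ = [
    "ConnectivityResult",
    "sttc",
    "sttc_matrix",
    "spectral_entropy_series",
    "corse",
    "corse_matrix",
    "connectivity_map",
    "average_corse",
    "analyze_connectivity",
]


@dataclass
class ConnectivityResult:
    """Pairwise CorSE and STTC for one well, with summaries and edges."""

    well_id: str
    electrode_ids: list[str]
    sttc_matrix: np.ndarray | None = None
    corse_matrix: np.ndarray | None = None
    well_sttc_summary: float | None = None
    well_avg_corse: float | None = None
    #: (electrode_a, electrode_b, corse) with a < b, corse > edge threshold
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.electrode_ids
        rows = []
        for i, j in combinations(range(len(ids)), 2):
            a, b = sorted((ids[i], ids[j]))
            cv = np.nan if self.corse_matrix is None else self.corse_matrix[i, j]
            sv = np.nan if self.sttc_matrix is None else self.sttc_matrix[i, j]
            rows.append((self.well_id, a, b, cv, sv))
        return pd.DataFrame(rows, columns=CONN_HEADER)


# ---------------------------------------------------------------------------
# STTC
# ---------------------------------------------------------------------------


def _tiled_fraction(train: np.ndarray, dt: float, duration: float) -> float:
    """Fraction of [0, duration] covered by ±dt windows around the spikes."""
    if train.size == 0:
        return 0.0
    gaps = np.diff(train)
    covered = 2 * dt + float(np.minimum(gaps, 2 * dt).sum())
    covered -= max(0.0, dt - train[0])             # clip before 0
    covered -= max(0.0, (train[-1] + dt) - duration)  # clip after duration
    return covered / duration


def _prop_within(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Fraction of a's spikes within dt of some spike of b."""
    if a.size == 0:
        return 0.0
    if b.size == 0:
        return 0.0
    idx = np.searchsorted(b, a)
    left = np.where(idx > 0, a - b[np.clip(idx - 1, 0, b.size - 1)], np.inf)
    right = np.where(idx < b.size, b[np.clip(idx, 0, b.size - 1)] - a, np.inf)
    nearest = np.minimum(left, right)
    return float(np.count_nonzero(nearest <= dt)) / a.size


def sttc(
    train_a: np.ndarray,
    train_b: np.ndarray,
    dt: float = 0.05,
    duration: float = 600.0,
) -> float | None:
    """Spike time tiling coefficient of two sorted trains on [0, duration].

    Returns None when either train is empty (the coefficient is undefined).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if not 0 < dt < duration / 2:
        raise ValueError("require 0 < dt < duration/2")
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return None
    ta = _tiled_fraction(a, dt, duration)
    tb = _tiled_fraction(b, dt, duration)
    pa = _prop_within(a, b, dt)
    pb = _prop_within(b, a, dt)
    terms = []
    if 1.0 - pa * tb != 0.0:
        terms.append((pa - tb) / (1.0 - pa * tb))
    if 1.0 - pb * ta != 0.0:
        terms.append((pb - ta) / (1.0 - pb * ta))
    if not terms:
        return None
    return float(np.mean(terms))


def sttc_matrix(
    table: SpikeTable,
    well_id: str,
    params: SttcConfig | None = None,
    electrode_ids: list[str] | None = None,
) -> tuple[np.ndarray, float | None, list[str]]:
    """STTC over all unordered electrode pairs of a well, plus a summary.

    The summary over pairs is the median (or mean, per config); pairs with
    an undefined coefficient are excluded. The diagonal is 1 for non-empty
    trains, NaN otherwise.
    """
    params = params or SttcConfig()
    ids = electrode_ids if electrode_ids is not None else table.electrodes(well_id)
    n = len(ids)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        if table.train(well_id, ids[i]).size:
            mat[i, i] = 1.0
    for i, j in combinations(range(n), 2):
        v = sttc(
            table.train(well_id, ids[i]),
            table.train(well_id, ids[j]),
            params.dt_s,
            table.duration,
        )
        if v is not None:
            mat[i, j] = mat[j, i] = v
    off = mat[np.triu_indices(n, k=1)]
    off = off[~np.isnan(off)]
    if off.size == 0 or n < 2:
        summary = None
    elif params.summary == "mean":
        summary = float(np.mean(off))
    else:
        summary = float(np.median(off))
    return mat, summary, ids


# ---------------------------------------------------------------------------
# CorSE
# ---------------------------------------------------------------------------


def spectral_entropy_series(
    trace: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap_frac: float = 0.5,
    band: tuple[float, float] = (200.0, 3000.0),
) -> np.ndarray:
    """Normalized spectral entropy per (Hann-tapered) sliding window.

    Each window's periodogram is restricted to ``band`` and normalized to a
    probability distribution p_f; the entropy −Σ p_f log p_f / log N_f lies
    in [0, 1] (0 = pure tone, 1 = flat spectrum). Windows with zero power
    are assigned entropy 1 (maximal uncertainty) with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(window_s * fs))
    if nperseg < 64:
        raise ValueError("window must span at least 64 samples")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    noverlap = int(round(nperseg * overlap_frac))
    freqs, _, sxx = sps.spectrogram(
        trace,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        mode="psd",
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        raise ValueError("band contains no spectral bins for this window length")
    p = sxx[sel, :]
    totals = p.sum(axis=0)
    n_f = int(np.count_nonzero(sel))
    se = np.ones(p.shape[1])
    ok = totals > 0
    if np.any(~ok):
        warnings.warn("window(s) with zero in-band power: spectral entropy set to 1")
    q = p[:, ok] / totals[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)
    se[ok] = -terms.sum(axis=0) / np.log(n_f)
    return se


def corse(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    fs: float,
    params: CorseConfig | None = None,
    band: tuple[float, float] = (200.0, 3000.0),
) -> float | None:
    """CorSE connectivity strength: |Pearson r| of the two SE series.

    Returns None when either entropy series is constant (zero variance).
    """
    params = params or CorseConfig()
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.size != b.size:
        raise ValueError("traces must have equal length")
    se_a = spectral_entropy_series(a, fs, params.window_s, params.overlap_frac, band)
    se_b = spectral_entropy_series(b, fs, params.window_s, params.overlap_frac, band)
    if se_a.size < 10:
        raise ValueError("need at least 10 analysis windows")
    return _abs_corr(se_a, se_b)


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant spectral-entropy series: CorSE undefined")
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(abs(r))


def corse_matrix(
    recording: RawRecording,
    params: CorseConfig | None = None,
    band: tuple[float, float] = (200.0, 3000.0),
    prefilter: bool | None = None,
) -> tuple[np.ndarray, list[str]]:
    """CorSE over all electrode pairs of one well.

    Entropy series are computed once per channel (on the band-passed trace
    by default) and correlated pairwise. Diagonal is 1.
    """
    params = params or CorseConfig()
    if prefilter is None:
        prefilter = params.bandpass
    n = recording.n_electrodes
    series = []
    for row in range(n):
        tr = recording.traces[row]
        if prefilter:
            tr = bandpass_filter(tr, recording.fs, band[0], band[1])
        series.append(
            spectral_entropy_series(
                tr, recording.fs, params.window_s, params.overlap_frac, band
            )
        )
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i, j in combinations(range(n), 2):
        v = _abs_corr(series[i], series[j])
        if v is not None:
            mat[i, j] = mat[j, i] = v
    return mat, list(recording.electrode_ids)


def connectivity_map(
    corse_mat: np.ndarray,
    electrode_ids: list[str],
    edge_threshold: float = 0.7,
) -> list[tuple[str, str, float]]:
    """Pairs with CorSE strictly above the threshold, ordered with a < b."""
    edges = []
    n = len(electrode_ids)
    for i, j in combinations(range(n), 2):
        v = corse_mat[i, j]
        if not np.isnan(v) and v > edge_threshold:
            a, b = sorted((electrode_ids[i], electrode_ids[j]))
            edges.append((a, b, float(v)))
    return sorted(edges)


def average_corse(corse_mat: np.ndarray) -> float | None:
    """Mean over all defined unordered pair values (diagonal excluded)."""
    n = corse_mat.shape[0]
    off = corse_mat[np.triu_indices(n, k=1)]
    off = off[~np.isnan(off)]
    if off.size == 0:
        return None
    return float(np.mean(off))


def analyze_connectivity(
    table: SpikeTable | None,
    well_id: str,
    recording: RawRecording | None = None,
    sttc_params: SttcConfig | None = None,
    corse_params: CorseConfig | None = None,
    band: tuple[float, float] = (200.0, 3000.0),
    electrode_ids: list[str] | None = None,
) -> ConnectivityResult:
    """Joint STTC (from spikes) and CorSE (from raw traces) for one well."""
    corse_params = corse_params or CorseConfig()
    result = ConnectivityResult(well_id=well_id, electrode_ids=electrode_ids or [])
    if table is not None:
        mat, summary, ids = sttc_matrix(table, well_id, sttc_params, electrode_ids)
        result.sttc_matrix = mat
        result.well_sttc_summary = summary
        result.electrode_ids = ids
    if recording is not None:
        cmat, ids = corse_matrix(recording, corse_params, band)
        if result.electrode_ids and ids != result.electrode_ids:
            raise ValueError("raw and spike electrode orderings disagree")
        result.corse_matrix = cmat
        result.electrode_ids = ids
        result.well_avg_corse = average_corse(cmat)
        result.edges = connectivity_map(cmat, ids, corse_params.edge_threshold)
    return result
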