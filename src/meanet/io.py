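"""Readers and writers for the pipeline's on-disk formats, plus configuration.

Formats
-------
* Raw traces: HDF5, ``/wells/<well_id>/traces`` (float32 µV, electrodes ×
  samples), ``/wells/<well_id>/electrode_ids`` (strings), root attributes
  ``fs_hz`` and ``units`` = ``"uV"``.
* Spikes: CSV ``well_id,electrode_id,time_s`` (seconds, 6 decimals = 1 µs,
  sorted by well, electrode, time).
* Bursts: CSV ``well_id,electrode_id,t_start_s,t_end_s,n_spikes``.
* Connectivity: CSV ``well_id,electrode_a,electrode_b,corse,sttc`` with
  ``electrode_a < electrode_b`` lexicographically.
* Features: CSV with one row per (well, timepoint) and the 7 activity
  features.
* Config: YAML mirroring :class:`PipelineConfig`.

All time coordinates are 0-based seconds from recording start; burst
intervals are half-open ``[t_start, t_end)`` for bookkeeping purposes even
though both bounds coincide with member spike times.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RawRecording",
    "SpikeTable",
    "FormatError",
    "PipelineConfig",
    "FilterConfig",
    "ThresholdConfig",
    "SwtteoConfig",
    "ConsensusConfig",
    "ActivityConfig",
    "LogisiConfig",
    "SttcConfig",
    "CorseConfig",
    "PcaConfig",
    "read_raw",
    "write_raw",
    "read_raw_wells",
    "read_spikes",
    "write_spikes",
    "read_bursts",
    "write_bursts",
    "write_connectivity",
    "read_connectivity",
    "write_features",
    "read_features",
    "load_config",
    "save_config",
]

#: canonical feature column order (after well_id/timepoint)
FEATURE_COLUMNS = [
    "mfr_hz",
    "burst_rate_per_min",
    "burst_duration_s",
    "spike_freq_in_burst_hz",
    "spikes_in_burst",
    "pct_spikes_in_bursts",
    "sttc",
]

SPIKE_HEADER = ["well_id", "electrode_id", "time_s"]
BURST_HEADER = ["well_id", "electrode_id", "t_start_s", "t_end_s", "n_spikes"]
CONN_HEADER = ["well_id", "electrode_a", "electrode_b", "corse", "sttc"]


class FormatError(ValueError):
    """A file does not conform to one of the package's on-disk formats."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class RawRecording:
    """Multichannel voltage traces for one MEA well.

    Attributes
    ----------
    well_id : str
    electrode_ids : list of str, one per trace row, unique.
    traces : float ndarray, shape (n_electrodes, n_samples), µV.
    fs : float, sampling rate in Hz (12.5 kHz for the target hardware).
    t0 : float, recording start time in s (0 by default).
    """

    well_id: str
    electrode_ids: list[str]
    traces: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2 or self.traces.shape[1] < 1:
            raise ValueError("traces must be a 2-D (electrodes × samples) array")
        n = self.traces.shape[0]
        if not 1 <= n <= 64:
            raise ValueError(f"electrode count {n} outside 1..64")
        if len(self.electrode_ids) != n:
            raise ValueError("electrode_ids length does not match trace rows")
        if len(set(self.electrode_ids)) != n:
            raise ValueError("electrode_ids must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.fs

    @property
    def n_electrodes(self) -> int:
        return self.traces.shape[0]


@dataclass
class SpikeTable:
    """Sorted spike times per (well, electrode) with the recording duration.

    ``spikes`` maps ``(well_id, electrode_id)`` to a sorted float array of
    spike times in seconds within ``[0, duration]``.
    """

    duration: float
    spikes: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        clean: dict[tuple[str, str], np.ndarray] = {}
        for key, t in self.spikes.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(
                    f"spike times for electrode {key} not strictly increasing"
                )
            if t.size and (t[0] < 0 or t[-1] > self.duration + 1e-9):
                raise ValueError(f"spike times for electrode {key} outside [0, duration]")
            clean[key] = t
        self.spikes = clean

    # -- convenience ------------------------------------------------------
    def wells(self) -> list[str]:
        return sorted({w for w, _ in self.spikes})

    def electrodes(self, well_id: str) -> list[str]:
        return sorted(e for w, e in self.spikes if w == well_id)

    def train(self, well_id: str, electrode_id: str) -> np.ndarray:
        return self.spikes.get((well_id, electrode_id), np.empty(0))

    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))

    def subset(self, keys: Iterable[tuple[str, str]]) -> "SpikeTable":
        keys = set(keys)
        return SpikeTable(
            self.duration, {k: v for k, v in self.spikes.items() if k in keys}
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (w, e, t)
            for (w, e) in sorted(self.spikes)
            for t in self.spikes[(w, e)]
        ]
        return pd.DataFrame(rows, columns=SPIKE_HEADER)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, duration: float) -> "SpikeTable":
        spikes: dict[tuple[str, str], np.ndarray] = {}
        for (w, e), grp in df.groupby(["well_id", "electrode_id"], sort=True):
            t = grp["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise FormatError(
                    f"non-monotone spike times for well {w} electrode {e}"
                )
            spikes[(str(w), str(e))] = t
        return cls(duration=duration, spikes=spikes)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class FilterConfig:
    f_lo: float = 200.0          # Hz, lower passband edge
    f_hi: float = 3000.0         # Hz, upper passband edge
    order: int = 4
    ripple_db: float = 0.1       # passband ripple
    stop_db: float = 40.0        # stopband attenuation


@dataclass
class ThresholdConfig:
    k: float = 4.5               # multiples of the noise SD estimate
    dead_time_s: float = 0.001
    polarity: str = "neg"        # "neg" | "both"; extracellular spikes are negative-dominant


@dataclass
class SwtteoConfig:
    wavelet: str = "sym2"
    level: int = 3               # at 12.5 kHz the spike band sits in detail level 3
    smooth_window_samples: int = 25   # ≈2 ms at 12.5 kHz


@dataclass
class ConsensusConfig:
    tolerance_s: float = 0.001


@dataclass
class ActivityConfig:
    min_spikes_per_min: float = 10.0  # strict >


@dataclass
class LogisiConfig:
    bins_per_decade: int = 10
    void_threshold: float = 0.7
    max_core_isi_s: float = 0.1
    min_spikes: int = 5
    merge_gap_s: float = 0.1


@dataclass
class SttcConfig:
    dt_s: float = 0.05
    summary: str = "median"      # "median" | "mean" over pairs


@dataclass
class CorseConfig:
    window_s: float = 1.0
    overlap_frac: float = 0.5
    edge_threshold: float = 0.7
    bandpass: bool = True        # compute SE on the filtered trace


@dataclass
class PcaConfig:
    n_components: int = 3
    population_sd: bool = True   # z-score with 1/n variance


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    swtteo: SwtteoConfig = field(default_factory=SwtteoConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    logisi: LogisiConfig = field(default_factory=LogisiConfig)
    sttc: SttcConfig = field(default_factory=SttcConfig)
    corse: CorseConfig = field(default_factory=CorseConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    seed: int = 0

    def validate(self, fs: float | None = None) -> None:
        f = self.filter
        if not 0 < f.f_lo < f.f_hi:
            raise ValueError("require 0 < f_lo < f_hi")
        if fs is not None and not f.f_hi < fs / 2:
            raise ValueError("f_hi must be below the Nyquist frequency")
        for name, v in [
            ("threshold.dead_time_s", self.threshold.dead_time_s),
            ("consensus.tolerance_s", self.consensus.tolerance_s),
            ("logisi.max_core_isi_s", self.logisi.max_core_isi_s),
            ("logisi.merge_gap_s", self.logisi.merge_gap_s),
            ("sttc.dt_s", self.sttc.dt_s),
            ("corse.window_s", self.corse.window_s),
        ]:
            if not v > 0:
                raise ValueError(f"{name} must be positive")
        if self.logisi.min_spikes < 2:
            raise ValueError("logisi.min_spikes must be ≥ 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        sections = {
            "filter": FilterConfig,
            "threshold": ThresholdConfig,
            "swtteo": SwtteoConfig,
            "consensus": ConsensusConfig,
            "activity": ActivityConfig,
            "logisi": LogisiConfig,
            "sttc": SttcConfig,
            "corse": CorseConfig,
            "pca": PcaConfig,
        }
        kwargs: dict = {}
        for key, val in d.items():
            if key in sections:
                klass = sections[key]
                valid = {f.name for f in dataclasses.fields(klass)}
                bad = set(val) - valid
                if bad:
                    raise FormatError(
                        f"unknown config key(s) {sorted(bad)} in section '{key}'"
                    )
                kwargs[key] = klass(**val)
            elif key == "seed":
                kwargs["seed"] = int(val)
            else:
                raise FormatError(f"unknown config section '{key}'")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError("config file must contain a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# raw HDF5
# ---------------------------------------------------------------------------


def write_raw(
    recordings: RawRecording | Iterable[RawRecording],
    path: str | Path,
    overwrite: bool = True,
) -> Path:
    """Write one or more well recordings to the HDF5 layout."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise OSError(f"{path} exists and overwrite is not set")
    if isinstance(recordings, RawRecording):
        recordings = [recordings]
    recordings = list(recordings)
    if not recordings:
        raise ValueError("nothing to write")
    fs = recordings[0].fs
    with h5py.File(path, "w") as fh:
        fh.attrs["fs_hz"] = float(fs)
        fh.attrs["units"] = "uV"
        wells = fh.create_group("wells")
        for rec in recordings:
            if rec.fs != fs:
                raise ValueError("all wells in one file must share fs")
            grp = wells.create_group(rec.well_id)
            grp.create_dataset("traces", data=rec.traces.astype(np.float32))
            grp.create_dataset(
                "electrode_ids",
                data=np.array(rec.electrode_ids, dtype=h5py.string_dtype()),
            )
    return path


def _read_one_well(fh: h5py.File, well_id: str, fs: float) -> RawRecording:
    grp = fh["wells"][well_id]
    if "traces" not in grp:
        raise FormatError(f"missing dataset /wells/{well_id}/traces")
    if "electrode_ids" not in grp:
        raise FormatError(f"missing dataset /wells/{well_id}/electrode_ids")
    traces = np.asarray(grp["traces"], dtype=np.float32)
    ids = [
        s.decode() if isinstance(s, bytes) else str(s)
        for s in np.asarray(grp["electrode_ids"])
    ]
    if traces.ndim != 2:
        raise FormatError(f"/wells/{well_id}/traces is not 2-D (ragged rows?)")
    try:
        return RawRecording(well_id=well_id, electrode_ids=ids, traces=traces, fs=fs)
    except ValueError as exc:
        raise FormatError(f"invalid well {well_id}: {exc}") from exc


def read_raw(path: str | Path, well_id: str | None = None) -> RawRecording:
    """Read one well; if ``well_id`` is None the file must hold exactly one."""
    with h5py.File(path, "r") as fh:
        if "fs_hz" not in fh.attrs:
            raise FormatError("missing root attribute fs_hz")
        fs = float(fh.attrs["fs_hz"])
        if "wells" not in fh:
            raise FormatError("missing group /wells")
        names = sorted(fh["wells"].keys())
        if well_id is None:
            if len(names) != 1:
                raise FormatError(
                    f"file holds {len(names)} wells; specify well_id from {names}"
                )
            well_id = names[0]
        if well_id not in names:
            raise FormatError(f"missing group /wells/{well_id}")
        return _read_one_well(fh, well_id, fs)


def read_raw_wells(path: str | Path) -> dict[str, RawRecording]:
    """Read all wells in a raw file, keyed by well id."""
    with h5py.File(path, "r") as fh:
        if "fs_hz" not in fh.attrs:
            raise FormatError("missing root attribute fs_hz")
        fs = float(fh.attrs["fs_hz"])
        if "wells" not in fh:
            raise FormatError("missing group /wells")
        return {w: _read_one_well(fh, w, fs) for w in sorted(fh["wells"].keys())}


# ---------------------------------------------------------------------------
# spike CSV
# ---------------------------------------------------------------------------


def write_spikes(table: SpikeTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(",".join(SPIKE_HEADER) + "\n")
        for (w, e) in sorted(table.spikes):
            for t in table.spikes[(w, e)]:
                fh.write(f"{w},{e},{t:.6f}\n")
    return path


def read_spikes(path: str | Path, duration: float) -> SpikeTable:
    """Read a spike CSV; ``duration`` is the recording length in seconds.

    Times are parsed at 1 µs resolution; per-electrode monotonicity is
    enforced (a violation names the offending electrode).
    """
    df = pd.read_csv(path, dtype={"well_id": str, "electrode_id": str})
    if list(df.columns) != SPIKE_HEADER:
        raise FormatError(f"spike CSV header must be {SPIKE_HEADER}")
    df["time_s"] = df["time_s"].round(6)
    return SpikeTable.from_dataframe(df, duration=duration)


# ---------------------------------------------------------------------------
# burst CSV
# ---------------------------------------------------------------------------


def write_bursts(burst_rows: pd.DataFrame, path: str | Path) -> Path:
    """Write a burst table (columns = BURST_HEADER)."""
    if list(burst_rows.columns) != BURST_HEADER:
        raise ValueError(f"burst table columns must be {BURST_HEADER}")
    path = Path(path)
    out = burst_rows.copy()
    out["t_start_s"] = out["t_start_s"].map(lambda v: f"{v:.6f}")
    out["t_end_s"] = out["t_end_s"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def read_bursts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well_id": str, "electrode_id": str})
    if list(df.columns) != BURST_HEADER:
        raise FormatError(f"burst CSV header must be {BURST_HEADER}")
    return df


# ---------------------------------------------------------------------------
# connectivity / feature CSV
# ---------------------------------------------------------------------------


def write_connectivity(rows: pd.DataFrame, path: str | Path) -> Path:
    if list(rows.columns) != CONN_HEADER:
        raise ValueError(f"connectivity columns must be {CONN_HEADER}")
    bad = rows[rows["electrode_a"] >= rows["electrode_b"]]
    if len(bad):
        raise ValueError("require electrode_a < electrode_b lexicographically")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False, lineterminator="\n")
    return Path(path)


def read_connectivity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well_id": str, "electrode_a": str, "electrode_b": str})
    if list(df.columns) != CONN_HEADER:
        raise FormatError(f"connectivity CSV header must be {CONN_HEADER}")
    return df


def write_features(rows: pd.DataFrame, path: str | Path) -> Path:
    expected = ["well_id", "timepoint"] + FEATURE_COLUMNS
    if list(rows.columns) != expected:
        raise ValueError(f"feature columns must be {expected}")
    rows.to_csv(path, index=False, lineterminator="\n")
    return Path(path)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well_id": str, "timepoint": str})
    expected = ["well_id", "timepoint"] + FEATURE_COLUMNS
    if list(df.columns) != expected:
        raise FormatError(f"feature CSV header must be {expected}")
    return df
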