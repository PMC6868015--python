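"""Well-level activity features, PCA projection, and pharmacology summaries.

Seven features summarize each well at each time point: mean firing rate
(MFR) over active electrodes, burst rate, burst duration, spike frequency
in bursts, spikes per burst, percentage of spikes in bursts, and the
median pairwise STTC. Feature vectors are standard-score normalized and
projected onto principal components; group segregation in the leading
components is quantified by the mean silhouette coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .io import FEATURE_COLUMNS, SpikeTable

__all__ = [
    "FeatureVector",
    "PcaResult",
    "mean_firing_rate",
    "build_feature_matrix",
    "zscore",
    "pca_project",
    "group_separation",
    "percent_change",
]

log = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    """The 7 activity features for one well at one time point."""

    well_id: str
    timepoint: str
    mfr_hz: float | None = None
    burst_rate_per_min: float | None = None
    burst_duration_s: float | None = None
    spike_freq_in_burst_hz: float | None = None
    spikes_in_burst: float | None = None
    pct_spikes_in_bursts: float | None = None
    sttc: float | None = None

    def values(self) -> list[float | None]:
        return [getattr(self, c) for c in FEATURE_COLUMNS]

    @property
    def complete(self) -> bool:
        return all(v is not None and np.isfinite(v) for v in self.values())


@dataclass
class PcaResult:
    """Scores, loadings and explained variance of a PCA projection."""

    scores: np.ndarray          # samples × kept components
    explained_pct: np.ndarray   # ALL components; sums to 100
    loadings: np.ndarray        # kept components × features
    labels: list[str]           # group label per sample, carried through


def mean_firing_rate(
    table: SpikeTable,
    well_id: str,
    duration: float,
    active_mask: dict[tuple[str, str], bool],
) -> float | None:
    """Mean over active electrodes of spike count / duration (Hz)."""
    if not duration > 0:
        raise ValueError("duration must be positive")
    rates = [
        table.train(well_id, e).size / duration
        for (w, e), active in active_mask.items()
        if w == well_id and active
    ]
    if not rates:
        return None
    return float(np.mean(rates))


def build_feature_matrix(
    vectors: list[FeatureVector],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack complete feature vectors into a samples × 7 matrix.

    Samples missing any feature are dropped with a logged reason; columns
    follow the canonical order of :data:`meanet.io.FEATURE_COLUMNS`.
    """
    rows, meta = [], []
    for v in vectors:
        if not v.complete:
            missing = [c for c, val in zip(FEATURE_COLUMNS, v.values()) if val is None]
            log.info(
                "dropping well %s / %s: missing %s", v.well_id, v.timepoint, missing
            )
            continue
        rows.append([float(x) for x in v.values()])
        meta.append((v.well_id, v.timepoint))
    if not rows:
        raise ValueError("no complete feature vectors: nothing to analyze")
    matrix = np.asarray(rows, dtype=float)
    labels = pd.DataFrame(meta, columns=["well_id", "timepoint"])
    return matrix, labels


def zscore(
    matrix: np.ndarray,
    population_sd: bool = True,
    feature_names: list[str] | None = None,
) -> np.ndarray:
    """Standard-score each column to mean 0, SD 1 (population SD by default)."""
    matrix = np.asarray(matrix, dtype=float)
    names = feature_names or FEATURE_COLUMNS
    sd = matrix.std(axis=0, ddof=0 if population_sd else 1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = [names[i] if i < len(names) else str(i) for i in zero]
        raise ValueError(f"zero-variance feature column(s): {bad}")
    return (matrix - matrix.mean(axis=0)) / sd


def pca_project(matrix: np.ndarray, n_components: int = 3) -> PcaResult:
    """Project z-scored samples onto principal components.

    Components come from the sample covariance of the input, sorted by
    decreasing variance; each component's sign is fixed so its largest-
    magnitude loading is positive. ``explained_pct`` covers every
    component (summing to 100) even when fewer are kept; if the matrix has
    rank below ``n_components`` the surplus components carry ~0% variance
    and a warning is logged.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if n < n_components:
        raise ValueError("need at least n_components samples")
    pca = PCA(n_components=None)
    scores = pca.fit_transform(matrix)
    loadings = pca.components_
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.arange(loadings.shape[0]), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    explained_pct = 100.0 * pca.explained_variance_ratio_
    k = min(n_components, loadings.shape[0])
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * max(1.0, pca.explained_variance_[0])))
    if rank < n_components:
        log.warning("matrix rank %d below requested %d components", rank, n_components)
    return PcaResult(
        scores=scores[:, :k],
        explained_pct=explained_pct,
        loadings=loadings[:k],
        labels=[],
    )


def group_separation(
    scores: np.ndarray,
    labels: list[str] | np.ndarray,
    k: int = 3,
) -> float:
    """Mean silhouette coefficient of the labeled groups in the first k PCs.

    Samples in singleton groups get coefficient 0 (logged). Requires at
    least two distinct labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two distinct group labels")
    if np.any(counts == 1):
        log.info("singleton group(s) %s: silhouette defined as 0", uniq[counts == 1])
    x = scores[:, : min(k, scores.shape[1])]
    return float(np.mean(silhouette_samples(x, labels)))


def percent_change(baseline_rate: float, treatment_rate: float) -> float | None:
    """Percent change of a rate versus its same-well baseline.

    None (logged) when the baseline is zero — the change is undefined.
    """
    if baseline_rate < 0 or treatment_rate < 0:
        raise ValueError("rates must be non-negative")
    if baseline_rate == 0:
        log.info("zero baseline rate: percent change undefined")
        return None
    return 100.0 * (treatment_rate - baseline_rate) / baseline_rate
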