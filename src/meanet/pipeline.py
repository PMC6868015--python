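"""End-to-end orchestration: detect → bursts → connectivity → features → PCA.

A run consumes either raw traces (HDF5) or an already-detected spike table
(CSV), executes the downstream stages, writes every stage's table under an
output directory, and finishes with a JSON manifest recording the config
snapshot, input hashes, seed, per-stage record counts and output hashes.

Only active electrodes (>10 spikes/min) enter burst, synchrony and firing-
rate analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .bursts import analyze_bursts, bursts_to_dataframe, burst_features, well_aggregate
from .connectivity import analyze_connectivity
from .detection import active_electrodes, detect_spikes
from .features import (
    FeatureVector,
    build_feature_matrix,
    mean_firing_rate,
    pca_project,
    zscore,
)
from .io import (
    FEATURE_COLUMNS,
    PipelineConfig,
    RawRecording,
    SpikeTable,
    read_raw_wells,
    read_spikes,
    write_bursts,
    write_connectivity,
    write_features,
    write_spikes,
)

__all__ = ["PipelineError", "analyze_table", "well_feature_vector", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def well_feature_vector(
    table: SpikeTable,
    well_id: str,
    timepoint: str,
    config: PipelineConfig,
    electrode_ids: list[str] | None = None,
) -> FeatureVector:
    """Compute the 7-feature vector for one well at one time point.

    Burst and STTC stages run on active electrodes only; features that
    cannot be computed (no active or no bursting electrodes) are left None
    and the sample is later dropped from the PCA matrix.
    """
    layout = {well_id: electrode_ids} if electrode_ids is not None else None
    mask, _ = active_electrodes(table, config.activity.min_spikes_per_min, layout)
    active_keys = [k for k, v in mask.items() if v and k[0] == well_id]
    sub = table.subset(active_keys)
    fv = FeatureVector(well_id=well_id, timepoint=timepoint)
    fv.mfr_hz = mean_firing_rate(table, well_id, table.duration, mask)

    bsets = analyze_bursts(sub, config.logisi)
    bset = bsets.get(well_id)
    if bset is not None and bset.bursts:
        per_el = {}
        for eid, blist in bset.bursts.items():
            feats = burst_features(blist, sub.train(well_id, eid), sub.duration)
            if feats is not None:
                per_el[eid] = feats
        agg = well_aggregate(per_el)
        if agg is not None:
            for k, v in agg.items():
                setattr(fv, k, v)

    if len(sub.electrodes(well_id)) >= 2:
        conn = analyze_connectivity(sub, well_id, sttc_params=config.sttc)
        fv.sttc = conn.well_sttc_summary
    return fv


def analyze_table(
    table: SpikeTable,
    config: PipelineConfig,
    timepoint: str = "t0",
    electrode_layout: dict[str, list[str]] | None = None,
) -> tuple[list[FeatureVector], pd.DataFrame, pd.DataFrame]:
    """Bursts + synchrony + features for every well in a spike table.

    Returns (feature vectors, burst table, connectivity table).
    """
    mask, _ = active_electrodes(table, config.activity.min_spikes_per_min, electrode_layout)
    sub = table.subset([k for k, v in mask.items() if v])
    bsets = analyze_bursts(sub, config.logisi)
    burst_df = bursts_to_dataframe(bsets)
    conn_frames, vectors = [], []
    for well in sorted({w for w, _ in table.spikes}):
        ids = electrode_layout.get(well) if electrode_layout else None
        vectors.append(well_feature_vector(table, well, timepoint, config, ids))
        if len(sub.electrodes(well)) >= 2:
            conn = analyze_connectivity(sub, well, sttc_params=config.sttc)
            conn_frames.append(conn.to_dataframe())
    conn_df = (
        pd.concat(conn_frames, ignore_index=True)
        if conn_frames
        else pd.DataFrame(columns=["well_id", "electrode_a", "electrode_b", "corse", "sttc"])
    )
    return vectors, burst_df, conn_df


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    raw_path: str | Path | None = None,
    spikes_path: str | Path | None = None,
    duration: float | None = None,
    timepoint: str = "t0",
    seed: int | None = None,
) -> dict:
    """Run the full pipeline and write all stage outputs plus a manifest.

    Exactly one of ``raw_path`` / ``spikes_path`` must be given; reading
    from a spike CSV requires ``duration``. Returns the manifest dict.
    """
    if (raw_path is None) == (spikes_path is None):
        raise ValueError("provide exactly one of raw_path or spikes_path")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    seed = config.seed if seed is None else seed

    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "inputs": {},
        "outputs": {},
        "counts": {},
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    written: list[Path] = []

    def emit(name: str, writer, obj) -> Path:
        path = outdir / name
        writer(obj, path)
        written.append(path)
        return path

    stage = "load"
    try:
        if raw_path is not None:
            manifest["inputs"]["raw"] = _sha256(Path(raw_path))
            wells = read_raw_wells(raw_path)
            stage = "detect"
            spikes: dict = {}
            reports = []
            layout = {}
            for well_id, rec in wells.items():
                res = detect_spikes(rec, config)
                spikes.update(res.spikes.spikes)
                rep = res.per_electrode.copy()
                rep.insert(0, "well_id", well_id)
                reports.append(rep)
                layout[well_id] = list(rec.electrode_ids)
            any_rec: RawRecording = next(iter(wells.values()))
            table = SpikeTable(duration=any_rec.duration, spikes=spikes)
            emit("spikes.csv", lambda t, p: write_spikes(t, p), table)
            report_df = pd.concat(reports, ignore_index=True)
            emit(
                "detection_report.csv",
                lambda d, p: d.to_csv(p, index=False, lineterminator="\n"),
                report_df,
            )
            manifest["counts"]["electrodes"] = int(len(report_df))
        else:
            if duration is None:
                raise ValueError("duration is required when reading a spike CSV")
            manifest["inputs"]["spikes"] = _sha256(Path(spikes_path))
            table = read_spikes(spikes_path, duration)
            layout = None
        manifest["counts"]["spikes"] = table.n_spikes()

        stage = "bursts"
        vectors, burst_df, conn_df = analyze_table(table, config, timepoint, layout)
        emit("bursts.csv", write_bursts, burst_df)
        manifest["counts"]["bursts"] = int(len(burst_df))

        stage = "connectivity"
        emit("connectivity.csv", write_connectivity, conn_df)
        manifest["counts"]["electrode_pairs"] = int(len(conn_df))

        stage = "features"
        feat_df = pd.DataFrame(
            [[v.well_id, v.timepoint] + v.values() for v in vectors],
            columns=["well_id", "timepoint"] + FEATURE_COLUMNS,
        )
        emit("features.csv", write_features, feat_df)
        manifest["counts"]["feature_rows"] = int(len(feat_df))

        stage = "pca"
        complete = [v for v in vectors if v.complete]
        if len(complete) >= 2:
            try:
                matrix, meta = build_feature_matrix(complete)
                z = zscore(matrix, config.pca.population_sd)
                res = pca_project(z, config.pca.n_components)
                scores = pd.concat(
                    [
                        meta,
                        pd.DataFrame(
                            res.scores,
                            columns=[f"pc{i + 1}" for i in range(res.scores.shape[1])],
                        ),
                    ],
                    axis=1,
                )
                emit(
                    "pca_scores.csv",
                    lambda d, p: d.to_csv(p, index=False, lineterminator="\n"),
                    scores,
                )
                expl = pd.DataFrame(
                    {
                        "component": [f"pc{i + 1}" for i in range(res.explained_pct.size)],
                        "explained_pct": res.explained_pct,
                    }
                )
                emit(
                    "pca_explained.csv",
                    lambda d, p: d.to_csv(p, index=False, lineterminator="\n"),
                    expl,
                )
            except ValueError as exc:
                log.info("PCA skipped: %s", exc)
        else:
            log.info("PCA skipped: fewer than 2 complete samples")
    except Exception as exc:
        for path in written:
            path.rename(path.with_suffix(path.suffix + ".partial"))
        raise PipelineError(stage, exc) from exc

    stage = "manifest"
    manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    for path in written:
        manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
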