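"""End-to-end orchestration: simulate → epoch → train → explain →
cluster → deconvolve → report.

Each stage writes its artifacts into its own subdirectory of the output
directory; a manifest records parameters, seeds, and content hashes of
every written file so a re-run with the same configuration can be
audited for bit-identical simulated inputs and deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .classifier import (AugmentConfig, GROUP_LABELS, averaged_input,
                         evaluate, predict_subjects, split_datasets,
                         subject_cell_epochs, train_cell_model)
from .clustering import cluster_stats, label_clusters, morphological_open, threshold_map
from .deconvolution import (build_fir_design, fit_fir, group_hrf_summary,
                            hrf_features, roi_timecourse)
from .events import CONDITIONS, HEMIFIELDS, events_to_bids
from .hrf import GroupHRFOffsets
from .nn import Hyperparams
from .relevance import aggregate_heatmaps, dtd_heatmap
from .simulate import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageFailure", "run_pipeline", "write_report"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Serializable parameters for every stage."""

    out_dir: str = "pipeline_out"
    rng_seed: int = 0
    # simulation
    n_per_group: int = 20
    volume_shape: tuple[int, int, int] = (16, 16, 16)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    amplitude_ratio: float = 0.7
    latency_shift_s: float = 2.5
    undershoot_ratio_scale: float = 0.4
    # epoching / classification
    epoch_len_trs: int = 8
    test_fraction: float = 0.2
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    channels: tuple[int, ...] = (8, 8, 16, 16, 32)
    # clustering / deconvolution
    threshold_percentile: float = 95.0
    min_cluster_size: int = 20
    connectivity: int = 26
    fir_coverage_s: float = 20.0
    write_niftis: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        raw["hyperparams"] = Hyperparams(**raw["hyperparams"])
        aug = raw["augment"]
        aug["subsample_sizes"] = tuple(aug["subsample_sizes"])
        raw["augment"] = AugmentConfig(**aug)
        raw["volume_shape"] = tuple(raw["volume_shape"])
        raw["channels"] = tuple(raw["channels"])
        return cls(**raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    A stage failure halts the pipeline with :class:`StageFailure`; the
    partial outputs and a machine-readable error record are retained in
    the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}
    stage = "init"

    def record(stage_name: str, directory: Path, **info):
        files = {str(p.relative_to(out)): _hash_file(p)
                 for p in sorted(directory.rglob("*")) if p.is_file()}
        manifest["stages"][stage_name] = {"params_seen": True, **info}
        manifest["files"].update(files)

    try:
        # ---- simulate -------------------------------------------------
        stage = "simulate"
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        cohort_cfg = CohortConfig(
            n_per_group=config.n_per_group,
            volume_shape=config.volume_shape,
            effect_size=config.effect_size,
            noise_sd=config.noise_sd,
            patient_offsets=GroupHRFOffsets(
                amplitude_ratio=config.amplitude_ratio,
                latency_shift_s=config.latency_shift_s,
                undershoot_ratio_scale=config.undershoot_ratio_scale))
        runs, schedules, metadata, truth = simulate_cohort(
            cohort_cfg, rng_seed=config.rng_seed)
        metadata.to_csv(sim_dir / "participants.csv", index=False)
        for sid, sched in schedules.items():
            events_to_bids(sched, sim_dir / f"{sid}_events.tsv")
        if config.write_niftis:
            for run in runs:
                hio.save_run(run, sim_dir / f"{run.subject_id}_bold.nii.gz")
        record(stage, sim_dir, n_runs=len(runs), seed=config.rng_seed)

        # ---- epoch ----------------------------------------------------
        stage = "epoch"
        epoch_table, groups = subject_cell_epochs(
            runs, schedules, epoch_len_trs=config.epoch_len_trs)
        manifest["stages"]["epoch"] = {
            "n_cells": len(epoch_table),
            "epoch_len_trs": config.epoch_len_trs}

        # ---- split ----------------------------------------------------
        stage = "split"
        train_ids, test_ids = split_datasets(
            metadata, test_fraction=config.test_fraction,
            rng_seed=config.rng_seed + 1)
        split_dir = out / "split"
        split_dir.mkdir(exist_ok=True)
        (split_dir / "split.json").write_text(json.dumps(
            {"train": train_ids, "test": test_ids}, indent=2))
        record(stage, split_dir, n_train=len(train_ids),
               n_test=len(test_ids))

        # ---- train + evaluate per condition x hemifield ---------------
        stage = "train"
        from .nn import NetworkSpec
        metrics = {}
        heatmaps = []
        for ci, condition in enumerate(CONDITIONS):
            for hi, hemifield in enumerate(HEMIFIELDS):
                model_id = f"{condition}_{hemifield}"
                spec = NetworkSpec(
                    input_shape=(*config.volume_shape,
                                 config.epoch_len_trs),
                    channels=config.channels,
                    dropout_rate=config.hyperparams.dropout_rate)
                net = train_cell_model(
                    epoch_table, groups, train_ids, condition, hemifield,
                    config.hyperparams, spec=spec, augment=config.augment,
                    rng_seed=config.rng_seed + 10 * ci + hi)
                probs = predict_subjects(net, epoch_table, test_ids,
                                         condition, hemifield)
                labels = np.array([GROUP_LABELS[groups[s]]
                                   for s in test_ids])
                metrics[model_id] = evaluate(probs, labels).to_dict()
                stage = "relevance"
                for sid in test_ids:
                    x = averaged_input(
                        epoch_table[(sid, condition, hemifield)])
                    heatmaps.append(dtd_heatmap(net, x, subject_id=sid,
                                                model_id=model_id))
                stage = "train"
        train_dir = out / "train"
        train_dir.mkdir(exist_ok=True)
        (train_dir / "metrics.json").write_text(json.dumps(metrics,
                                                           indent=2))
        record("train", train_dir, n_models=len(metrics))

        # ---- aggregate relevance + cluster ----------------------------
        stage = "cluster"
        avg_map = aggregate_heatmaps(heatmaps, normalize_each=True)
        mask = threshold_map(avg_map, "percentile",
                             config.threshold_percentile)
        mask = morphological_open(mask)
        clusters = label_clusters(mask, connectivity=config.connectivity,
                                  min_size=config.min_cluster_size)
        table = cluster_stats(clusters, avg_map)
        cluster_dir = out / "cluster"
        cluster_dir.mkdir(exist_ok=True)
        table.to_csv(cluster_dir / "clusters.csv", index=False)
        if config.write_niftis:
            hio.save_label_volume(clusters.label_volume,
                                  cluster_dir / "labels.nii.gz")
        record(stage, cluster_dir, n_clusters=clusters.n_clusters)

        # ---- deconvolve -----------------------------------------------
        stage = "deconvolve"
        estimates = []
        for run in runs:
            design = build_fir_design(
                schedules[run.subject_id], run.tr_ms, run.n_volumes,
                coverage_s=config.fir_coverage_s)
            for _, rec in clusters.records.iterrows():
                cid = int(rec["id"])
                series = roi_timecourse(run, clusters.mask(cid))
                estimates.append(fit_fir(design, series, roi_id=cid,
                                         subject_id=run.subject_id,
                                         group=run.group))
        decon_dir = out / "deconvolve"
        decon_dir.mkdir(exist_ok=True)
        hrf_contrasts = None
        if estimates:
            summary = group_hrf_summary(estimates)
            summary.to_csv(decon_dir / "group_hrf.csv", index=False)
            hrf_contrasts = _feature_contrasts(summary, runs[0].tr_ms)
            (decon_dir / "hrf_features.json").write_text(
                json.dumps(hrf_contrasts, indent=2))
        record(stage, decon_dir, n_estimates=len(estimates))

        # ---- report ---------------------------------------------------
        stage = "report"
        write_report(metrics, table, hrf_contrasts, out / "report")
        record(stage, out / "report")

    except Exception as err:  # noqa: BLE001 - halt with stage context
        (out / "error.json").write_text(json.dumps(
            {"stage": stage, "error": str(err),
             "type": type(err).__name__}, indent=2))
        raise StageFailure(stage, err) from err

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _feature_contrasts(summary: pd.DataFrame, tr_ms: float) -> dict:
    """Group-mean HRF shape features per ROI × event type."""
    out: dict = {}
    tr_s = tr_ms / 1000.0
    for (group, roi, etype), sub in summary.groupby(
            ["group", "roi_id", "event_type"]):
        betas = sub.sort_values("lag_s")["mean"].to_numpy()
        try:
            feats = hrf_features(betas, tr_s)
        except ValueError:
            continue
        out.setdefault(f"roi{roi}_{etype}", {})[group] = {
            "peak_amplitude": feats.peak_amplitude,
            "time_to_peak_s": feats.time_to_peak_s,
            "time_to_peak_interp_s": feats.time_to_peak_interp_s,
            "undershoot_depth": feats.undershoot_depth,
        }
    return out


def write_report(metrics, cluster_table, hrf_contrasts,
                 report_dir: str | Path) -> Path:
    """JSON report of per-model metrics, clusters, and HRF contrasts.

    Sections whose inputs are missing are listed as "not run" instead of
    failing.
    """
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "metrics": metrics if metrics else "not run",
        "clusters": (cluster_table.to_dict(orient="records")
                     if cluster_table is not None else "not run"),
        "hrf_contrasts": (hrf_contrasts if hrf_contrasts is not None
                          else "not run"),
    }
    path = report_dir / "report.json"
    path.write_text(json.dumps(report, indent=2))
    if cluster_table is not None and len(cluster_table):
        cluster_table.to_csv(report_dir / "clusters.csv", index=False)
    return path
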