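"""Synthetic event-related BOLD runs with group-dependent ground truth.

Each run is a 4D volume series on a common space (inter-subject
registration is the identity).  Active regions respond to their selective
events through the subject's ground-truth HRF sampled on the TR grid;
every voxel carries baseline signal, white Gaussian noise, and an optional
linear drift.  Temporal autocorrelation is deliberately not modeled: the
study design this emulates applies high-pass filtering upstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import CONDITIONS, HEMIFIELDS, generate_event_schedule, validate_schedule
from .hrf import GroupHRFOffsets, HRFParams, apply_offsets, make_hrf

logger = logging.getLogger(__name__)

__all__ = [
    "BoldRun", "ActiveRegion", "ActivationSpec", "CohortConfig",
    "simulate_run", "simulate_cohort", "default_activation",
    "sample_hrf_at_tr", "DEFAULT_TR_MS", "DEFAULT_N_VOLUMES",
]

DEFAULT_TR_MS = 2500.0
DEFAULT_N_VOLUMES = 116


@dataclass
class BoldRun:
    """One subject's 4D volume series (x, y, z, t)."""

    data: np.ndarray
    tr_ms: float
    subject_id: str
    group: str
    space_tag: str = "synthetic-common"

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")
        if self.data.ndim != 4:
            raise ValueError("BoldRun data must be 4-D (x, y, z, t)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun intensities must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class ActiveRegion:
    """A 3D binary mask with event selectivity and an effect size.

    ``condition``/``hemifield`` of ``None`` means the region responds to
    every condition/hemifield.
    """

    mask: np.ndarray
    effect_size: float = 1.0
    condition: str | None = None
    hemifield: str | None = None

    def selects(self, condition: str, hemifield: str) -> bool:
        return ((self.condition is None or self.condition == condition)
                and (self.hemifield is None or self.hemifield == hemifield))


@dataclass
class ActivationSpec:
    """Ground-truth activation layout plus noise model for one run."""

    regions: list[ActiveRegion] = field(default_factory=list)
    baseline_level: float = 100.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_activation(
    volume_shape: tuple[int, int, int] = (16, 16, 16),
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
) -> ActivationSpec:
    """Two hemifield-selective cubic regions placed in opposite hemispheres.

    The left visual hemifield projects to the right hemisphere, so the
    left-hemifield region sits in the +x half of the volume.
    """
    nx, ny, nz = volume_shape
    side = max(2, min(4, nx // 4))
    y0, z0 = ny // 2 - side // 2, nz // 2 - side // 2
    regions = []
    for hemifield, x0 in (("left", 3 * nx // 4 - side // 2),
                          ("right", nx // 4 - side // 2)):
        mask = np.zeros(volume_shape, dtype=bool)
        mask[x0:x0 + side, y0:y0 + side, z0:z0 + side] = True
        regions.append(ActiveRegion(mask=mask, effect_size=effect_size,
                                    hemifield=hemifield))
    return ActivationSpec(regions=regions, noise_sd=noise_sd)


def sample_hrf_at_tr(params: HRFParams, tr_ms: float,
                     coverage_s: float = 20.0) -> np.ndarray:
    """Ground-truth HRF sampled on the TR grid over `coverage_s` seconds
    post-onset (the same support the FIR deconvolution models)."""
    n_lags = int(np.ceil(coverage_s * 1000.0 / tr_ms))
    times = np.arange(n_lags) * tr_ms / 1000.0
    return make_hrf(params, times)


def _stick_train(events: pd.DataFrame, condition: str | None,
                 hemifield: str | None, tr_ms: float,
                 n_volumes: int) -> np.ndarray:
    sticks = np.zeros(n_volumes)
    for _, ev in events.iterrows():
        if condition is not None and ev["condition"] != condition:
            continue
        if hemifield is not None and ev["hemifield"] != hemifield:
            continue
        idx = onset_to_index(ev["onset_ms"], tr_ms)
        if idx < n_volumes:
            sticks[idx] += 1.0
    return sticks


def onset_to_index(onset_ms: float, tr_ms: float) -> int:
    """Volume index of an onset; off-grid onsets round with a warning."""
    frac = onset_ms / tr_ms
    idx = int(round(frac))
    if abs(frac - idx) > 1e-6:
        logger.warning("onset %.1f ms not on the TR grid; rounding to "
                       "volume %d", onset_ms, idx)
    return idx


def simulate_run(
    schedule: pd.DataFrame,
    activation: ActivationSpec,
    group_hrfs: HRFParams | dict[str, HRFParams],
    tr_ms: float = DEFAULT_TR_MS,
    n_volumes: int = DEFAULT_N_VOLUMES,
    rng_seed: int | np.random.Generator = 0,
    volume_shape: tuple[int, int, int] = (16, 16, 16),
    subject_id: str = "sub-00",
    group: str = "control",
    hrf_coverage_s: float = 20.0,
    extend_run: bool = True,
) -> BoldRun:
    """Synthesize one BOLD run from an event schedule.

    `group_hrfs` is either a single :class:`HRFParams` used for every
    condition or a mapping condition → :class:`HRFParams`.  If the drawn
    schedule (plus HRF coverage) overruns `n_volumes`, the run is extended
    with a warning (set ``extend_run=False`` to make that a design error
    instead).
    """
    rng = np.random.default_rng(rng_seed)
    validate_schedule(schedule)
    if activation.regions:
        for region in activation.regions:
            if region.mask.shape != tuple(volume_shape):
                raise ValueError("activation mask shape does not match "
                                 "volume_shape")
    n_lags = int(np.ceil(hrf_coverage_s * 1000.0 / tr_ms))
    if len(schedule):
        last_idx = onset_to_index(schedule["onset_ms"].max(), tr_ms)
        needed = last_idx + n_lags
        if needed > n_volumes:
            if not extend_run:
                raise ValueError(
                    f"schedule needs {needed} volumes but the run has only "
                    f"{n_volumes} (extend_run disabled)")
            warnings.warn(
                f"schedule needs {needed} volumes to cover the last "
                f"response; extending run from {n_volumes}", stacklevel=2)
            n_volumes = needed

    data = np.full((*volume_shape, n_volumes), activation.baseline_level)
    if activation.noise_sd > 0:
        data = data + rng.normal(0.0, activation.noise_sd, size=data.shape)
    else:
        data = data.astype(float)
    if activation.drift_amplitude:
        slope = rng.uniform(-1.0, 1.0) * activation.drift_amplitude
        data += slope * np.linspace(0.0, 1.0, n_volumes)

    for region in activation.regions:
        signal = np.zeros(n_volumes)
        for condition in CONDITIONS:
            params = (group_hrfs[condition] if isinstance(group_hrfs, dict)
                      else group_hrfs)
            kernel = sample_hrf_at_tr(params, tr_ms, hrf_coverage_s)
            for hemifield in HEMIFIELDS:
                if not region.selects(condition, hemifield):
                    continue
                sticks = _stick_train(schedule, condition, hemifield,
                                      tr_ms, n_volumes)
                signal += np.convolve(sticks, kernel)[:n_volumes]
        data[region.mask] += region.effect_size * signal

    return BoldRun(data=data, tr_ms=tr_ms, subject_id=subject_id,
                   group=group)


@dataclass
class CohortConfig:
    """Study-level generator settings.

    Defaults emulate the study design: two groups whose active-voxel
    responses follow different HRFs, runs of 116 volumes at TR 2500 ms,
    2 conditions × 2 hemifields × 10 repetitions, and small subject-level
    HRF variability (5% amplitude SD, 0.25 s latency SD).
    """

    n_per_group: int = 20
    volume_shape: tuple[int, int, int] = (16, 16, 16)
    tr_ms: float = DEFAULT_TR_MS
    n_volumes: int = DEFAULT_N_VOLUMES
    n_reps_per_cell: int = 10
    effect_size: float = 1.0
    noise_sd: float = 1.0
    control_hrf: HRFParams = field(default_factory=HRFParams)
    patient_offsets: GroupHRFOffsets = field(default_factory=GroupHRFOffsets)
    amplitude_jitter_frac: float = 0.05
    latency_jitter_s: float = 0.25
    submax_gain: float = 1.0
    threshold_gain: float = 0.6


def _subject_hrf(base: HRFParams, cfg: CohortConfig,
                 rng: np.random.Generator) -> HRFParams:
    amp = base.amplitude * (1.0 + cfg.amplitude_jitter_frac * rng.normal())
    lat = max(0.0, base.latency_shift + cfg.latency_jitter_s * rng.normal())
    return replace(base, amplitude=amp, latency_shift=lat)


def simulate_cohort(
    config: CohortConfig | None = None,
    rng_seed: int | np.random.Generator = 0,
    **overrides,
) -> tuple[list[BoldRun], dict[str, pd.DataFrame], pd.DataFrame, dict]:
    """Simulate a two-group cohort.

    Returns ``(runs, schedules, metadata, truth)`` where `schedules` maps
    subject id → event table, `metadata` has columns (subject_id, group,
    age, gender), and `truth` records per-subject HRF parameters and the
    activation layout for downstream localization / recovery checks.

    The two conditions drive active regions with different gains
    (sub-maximum > threshold), mirroring the stimulus-contrast ordering of
    the behavioral task.
    """
    cfg = config or CohortConfig(**overrides)
    if config is not None and overrides:
        raise TypeError("pass either a CohortConfig or keyword overrides")
    if cfg.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(rng_seed)

    patient_hrf = apply_offsets(cfg.control_hrf, cfg.patient_offsets)
    base_activation = default_activation(cfg.volume_shape,
                                         effect_size=cfg.effect_size,
                                         noise_sd=cfg.noise_sd)
    gains = {"submax": cfg.submax_gain, "threshold": cfg.threshold_gain}

    runs: list[BoldRun] = []
    schedules: dict[str, pd.DataFrame] = {}
    meta_rows = []
    subject_truth = {}
    sid = 0
    for group, base in (("control", cfg.control_hrf),
                        ("patient", patient_hrf)):
        for _ in range(cfg.n_per_group):
            subject_id = f"sub-{sid:03d}"
            sid += 1
            hrf = _subject_hrf(base, cfg, rng)
            # gains realize the condition contrast; amplitude carries the
            # group difference and subject jitter
            cond_hrfs = {c: replace(hrf, amplitude=hrf.amplitude * g)
                         for c, g in gains.items()}
            schedule = generate_event_schedule(cfg.n_reps_per_cell, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                run = simulate_run(
                    schedule, base_activation, cond_hrfs,
                    tr_ms=cfg.tr_ms, n_volumes=cfg.n_volumes,
                    rng_seed=rng, volume_shape=cfg.volume_shape,
                    subject_id=subject_id, group=group)
            runs.append(run)
            schedules[subject_id] = schedule
            age = float(np.clip(rng.normal(55.0, 7.0), 40.0, 75.0))
            gender = "F" if rng.random() < 0.5 else "M"
            meta_rows.append((subject_id, group, age, gender))
            subject_truth[subject_id] = cond_hrfs

    metadata = pd.DataFrame(meta_rows,
                            columns=["subject_id", "group", "age", "gender"])
    truth = {
        "subject_hrfs": subject_truth,
        "group_hrfs": {"control": cfg.control_hrf, "patient": patient_hrf},
        "condition_gains": gains,
        "activation": base_activation,
        "config": cfg,
    }
    return runs, schedules, metadata, truth
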