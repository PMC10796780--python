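"""Event-locked epoching, averaging, normalization, and augmentation.

Runs are cropped around each stimulation event starting one volume before
onset (default 8 volumes, i.e. -2.5 s to +15 s at TR 2.5 s), averaged per
condition × hemifield, and z-normalized.  Training-time augmentation
re-draws a random subset of 7-9 of the 10 repetitions to average, and
applies small rigid geometric perturbations plus additive Gaussian noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .simulate import BoldRun, onset_to_index

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch", "crop_epochs", "average_epochs", "normalize_epoch",
    "count_subsets", "augment_subsample_average", "augment_geometric_noise",
    "DEFAULT_EPOCH_LEN",
]

DEFAULT_EPOCH_LEN = 8


@dataclass
class Epoch:
    """Event-locked 4D matrix (x, y, z, lag) for one condition × hemifield."""

    data: np.ndarray
    lag_times_s: np.ndarray
    condition: str
    hemifield: str
    n_averaged: int = 1
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("epoch data must be 4-D (x, y, z, lag)")
        if self.data.shape[3] != len(self.lag_times_s):
            raise ValueError("lag_times length must match the lag axis")


def crop_epochs(run: BoldRun, events, epoch_len_trs: int = DEFAULT_EPOCH_LEN):
    """Per-event epochs starting one volume before each onset.

    Events whose window falls outside the run are dropped with a warning.
    """
    if epoch_len_trs < 2:
        raise ValueError("epoch_len_trs must be >= 2")
    tr_s = run.tr_ms / 1000.0
    lag_times = (np.arange(epoch_len_trs) - 1) * tr_s
    epochs = []
    for _, ev in events.iterrows():
        onset_idx = onset_to_index(ev["onset_ms"], run.tr_ms)
        start = onset_idx - 1
        if start < 0 or start + epoch_len_trs > run.n_volumes:
            logger.warning(
                "dropping event at %.1f ms: window [%d, %d) outside run "
                "of %d volumes", ev["onset_ms"], start,
                start + epoch_len_trs, run.n_volumes)
            continue
        epochs.append(Epoch(
            data=run.data[..., start:start + epoch_len_trs].copy(),
            lag_times_s=lag_times,
            condition=ev["condition"],
            hemifield=ev["hemifield"],
        ))
    return epochs


def average_epochs(epochs: list[Epoch], subset=None) -> Epoch:
    """Voxelwise arithmetic mean over a subset of epochs (default: all)."""
    if not epochs:
        raise ValueError("no epochs to average")
    idx = list(range(len(epochs))) if subset is None else sorted(subset)
    if not idx:
        raise ValueError("empty subset")
    chosen = [epochs[i] for i in idx]
    first = chosen[0]
    for ep in chosen[1:]:
        if (ep.data.shape != first.data.shape
                or ep.condition != first.condition
                or ep.hemifield != first.hemifield):
            raise ValueError("epochs to average must share shape, "
                             "condition, and hemifield")
    mean = np.mean([ep.data for ep in chosen], axis=0)
    return replace(first, data=mean,
                   n_averaged=sum(ep.n_averaged for ep in chosen))


def normalize_epoch(epoch: Epoch) -> Epoch:
    """Scale to zero mean, unit variance over all voxels × lags."""
    sd = float(np.std(epoch.data))
    if sd < 1e-12:
        raise ValueError("cannot normalize a constant epoch (zero variance)")
    data = (epoch.data - np.mean(epoch.data)) / sd
    return replace(epoch, data=data, normalized=True)


def count_subsets(n: int, sizes=range(7, 10)) -> int:
    """Number of repetition subsets available to the averaging augmentation
    (175 for sizes 7-9 out of 10 repetitions)."""
    return sum(math.comb(n, k) for k in sizes)


def augment_subsample_average(
    per_event_epochs: list[Epoch],
    sizes=range(7, 10),
    rng_seed: int | np.random.Generator = 0,
) -> Epoch:
    """Average a subset drawn uniformly from all subsets of the given sizes.

    With the default 10 repetitions and sizes 7-9 the subset universe has
    175 elements; the draw is uniform over that universe, so subset sizes
    are chosen with probability proportional to their binomial counts.
    """
    n = len(per_event_epochs)
    sizes = list(sizes)
    if not sizes or n < min(sizes):
        raise ValueError(f"need at least {min(sizes) if sizes else 1} "
                         f"epochs, got {n}")
    rng = np.random.default_rng(rng_seed)
    counts = np.array([math.comb(n, k) for k in sizes], dtype=float)
    size = int(rng.choice(sizes, p=counts / counts.sum()))
    subset = rng.choice(n, size=size, replace=False)
    return average_epochs(per_event_epochs, subset=list(subset))


def augment_geometric_noise(
    epoch: Epoch,
    max_translation_voxels: float = 1.0,
    max_rotation_deg: float = 5.0,
    noise_sd: float = 0.1,
    rng_seed: int | np.random.Generator = 0,
    translation=None,
    rotation_deg: float | None = None,
    rotation_axes: tuple[int, int] | None = None,
) -> Epoch:
    """Random rigid shift + rotation (identical across lags) plus noise.

    Rotation uses trilinear interpolation with edge padding by the epoch
    mean, so augmented volumes stay in-distribution at the borders.
    Explicit `translation` / `rotation_deg` override the random draw
    (useful for reproducing a specific perturbation).
    """
    for name, v in (("max_translation_voxels", max_translation_voxels),
                    ("max_rotation_deg", max_rotation_deg),
                    ("noise_sd", noise_sd)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(rng_seed)
    shift = (np.asarray(translation, float) if translation is not None
             else rng.uniform(-max_translation_voxels,
                              max_translation_voxels, size=3))
    angle = (rotation_deg if rotation_deg is not None
             else rng.uniform(-max_rotation_deg, max_rotation_deg))
    axes = (rotation_axes if rotation_axes is not None
            else tuple(rng.choice(3, size=2, replace=False)))
    fill = float(np.mean(epoch.data))

    data = epoch.data
    if angle != 0:
        data = ndimage.rotate(data, angle, axes=axes, reshape=False,
                              order=1, mode="constant", cval=fill)
    if np.any(shift != 0):
        data = ndimage.shift(data, (*shift, 0.0), order=1,
                             mode="constant", cval=fill)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    if data is epoch.data:
        data = data.copy()
    return replace(epoch, data=data)
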