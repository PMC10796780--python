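"""Group classification from averaged event-locked epochs.

One model is trained and tested per condition × hemifield cell; the
classification unit is a subject's averaged epoch for that cell.  The
cohort is split 80/20 with the patient proportion forced equal in both
sets and a test set built from gender/age-matched cross-group pairs.
Training-time augmentation (repetition subsampling, rigid perturbation,
noise) is re-drawn per batch and never applied to tuning or test data.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             roc_auc_score)

from .epoching import (Epoch, augment_geometric_noise,
                       augment_subsample_average, average_epochs,
                       crop_epochs, normalize_epoch)
from .events import CONDITIONS, HEMIFIELDS
from .nn import Hyperparams, NetworkSpec, ResNet3d, train_network

logger = logging.getLogger(__name__)

__all__ = [
    "split_datasets", "build_network", "MetricsReport", "evaluate",
    "grid_search", "train_cell_model", "subject_cell_epochs",
    "AugmentConfig", "GROUP_LABELS",
]

#: label encoding: the patient group is the positive class
GROUP_LABELS = {"control": 0, "patient": 1}


# ---------------------------------------------------------------------
# dataset split with forced proportions and matched test pairs
# ---------------------------------------------------------------------
def split_datasets(
    subjects: pd.DataFrame,
    test_fraction: float = 0.2,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str]]:
    """Split subjects into train/test ids.

    The class (group) proportions are forced equal in both sets up to
    rounding.  The test set is assembled by repeatedly drawing a random
    unassigned subject and greedily pairing it with the closest
    opposite-group subject — exact gender match first, minimal age gap
    within gender; if the opposite group has no subject of that gender
    left, an age-only match is used with a warning.  Any remaining test
    quota of the larger class is filled by random draws from that class.
    """
    rng = np.random.default_rng(rng_seed)
    groups = subjects["group"].unique().tolist()
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    counts = subjects["group"].value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class to split")
    quota = {g: int(round(test_fraction * counts[g])) for g in groups}
    if min(quota.values()) < 1:
        raise ValueError(
            f"test_fraction {test_fraction} leaves no test subjects for "
            f"the smaller class (counts: {counts.to_dict()})")

    pool = {g: subjects[subjects["group"] == g].copy() for g in groups}
    test_ids: list[str] = []
    taken = {g: 0 for g in groups}

    n_pairs = min(quota.values())
    for _ in range(n_pairs):
        seed_group = groups[int(rng.integers(2))]
        other = groups[1 - groups.index(seed_group)]
        row = pool[seed_group].iloc[int(rng.integers(len(pool[seed_group])))]
        candidates = pool[other]
        same_gender = candidates[candidates["gender"] == row["gender"]]
        if len(same_gender):
            candidates = same_gender
        else:
            warnings.warn(
                f"no {row['gender']} subjects left in group {other}; "
                f"falling back to age-only matching", stacklevel=2)
        match = candidates.iloc[
            (candidates["age"] - row["age"]).abs().argmin()]
        for g, r in ((seed_group, row), (other, match)):
            test_ids.append(r["subject_id"])
            pool[g] = pool[g][pool[g]["subject_id"] != r["subject_id"]]
            taken[g] += 1

    for g in groups:  # unpaired remainder of the larger class quota
        while taken[g] < quota[g]:
            row = pool[g].iloc[int(rng.integers(len(pool[g])))]
            test_ids.append(row["subject_id"])
            pool[g] = pool[g][pool[g]["subject_id"] != row["subject_id"]]
            taken[g] += 1

    train_ids = [s for s in subjects["subject_id"] if s not in set(test_ids)]
    return train_ids, test_ids


# ---------------------------------------------------------------------
# epoch preparation per subject and cell
# ---------------------------------------------------------------------
def subject_cell_epochs(runs, schedules, epoch_len_trs: int = 8):
    """Per-event epochs keyed by (subject_id, condition, hemifield)."""
    table: dict[tuple[str, str, str], list[Epoch]] = {}
    groups: dict[str, str] = {}
    for run in runs:
        groups[run.subject_id] = run.group
        epochs = crop_epochs(run, schedules[run.subject_id], epoch_len_trs)
        for ep in epochs:
            key = (run.subject_id, ep.condition, ep.hemifield)
            table.setdefault(key, []).append(ep)
    return table, groups


def averaged_input(per_event: list[Epoch]) -> np.ndarray:
    """Normalized average of all repetitions — the tuning/test input."""
    return normalize_epoch(average_epochs(per_event)).data


@dataclass(frozen=True)
class AugmentConfig:
    subsample_sizes: tuple[int, ...] = (7, 8, 9)
    max_translation_voxels: float = 1.0
    max_rotation_deg: float = 5.0
    noise_sd: float = 0.1
    enabled: bool = True


def augmented_input(per_event: list[Epoch], cfg: AugmentConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """One freshly augmented, normalized training sample."""
    if not cfg.enabled:
        return averaged_input(per_event)
    sizes = [k for k in cfg.subsample_sizes if k <= len(per_event)]
    ep = augment_subsample_average(per_event, sizes or [len(per_event)], rng)
    ep = augment_geometric_noise(
        ep, cfg.max_translation_voxels, cfg.max_rotation_deg,
        cfg.noise_sd, rng)
    return normalize_epoch(ep).data


# ---------------------------------------------------------------------
# model construction / training / evaluation
# ---------------------------------------------------------------------
def build_network(spec: NetworkSpec,
                  rng_seed: int | np.random.Generator = 0) -> ResNet3d:
    """Untrained network with Glorot-uniform weights and zero biases."""
    return ResNet3d(spec, rng_seed=rng_seed)


def train_cell_model(
    epoch_table, groups, train_ids, condition: str, hemifield: str,
    hp: Hyperparams, spec: NetworkSpec | None = None,
    augment: AugmentConfig | None = None,
    rng_seed: int = 0,
) -> ResNet3d:
    """Train one condition × hemifield model on the given subjects."""
    augment = augment or AugmentConfig()
    ids = [s for s in train_ids if (s, condition, hemifield) in epoch_table]
    labels = np.array([GROUP_LABELS[groups[s]] for s in ids], float)
    if len(ids) == 0:
        raise ValueError(f"no training subjects for cell "
                         f"({condition}, {hemifield})")
    sample = epoch_table[(ids[0], condition, hemifield)][0]
    if spec is None:
        spec = NetworkSpec(input_shape=(*sample.data.shape[:3],
                                        sample.data.shape[3]),
                           dropout_rate=hp.dropout_rate)
    else:
        spec = replace(spec, dropout_rate=hp.dropout_rate)
    net = build_network(spec, rng_seed=rng_seed)

    def batch_fn(indices, rng):
        return np.stack([
            augmented_input(epoch_table[(ids[i], condition, hemifield)],
                            augment, rng)
            for i in indices])

    return train_network(net, None, labels, hp, rng_seed=rng_seed + 1,
                         batch_fn=batch_fn)


def predict_subjects(net: ResNet3d, epoch_table, ids, condition, hemifield):
    inputs = np.stack([
        averaged_input(epoch_table[(s, condition, hemifield)]) for s in ids])
    return net.predict_proba(inputs)


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auc", "accuracy", "f1", "sensitivity", "specificity",
                 "balanced_accuracy", "n")}


def evaluate(probabilities: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> MetricsReport:
    """Standard binary metrics at the given probability cut.

    AUC needs both classes; a single-class set raises while the other
    metrics would still be defined.
    """
    y = np.asarray(labels, int)
    p = np.asarray(probabilities, float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    pred = (p >= threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return MetricsReport(
        auc=float(roc_auc_score(y, p)),
        accuracy=float(accuracy_score(y, pred)),
        f1=float(f1_score(y, pred, zero_division=0)),
        sensitivity=float(sens),
        specificity=float(spec),
        balanced_accuracy=float((sens + spec) / 2.0),
        n=len(y),
    )


# ---------------------------------------------------------------------
# hyperparameter grid search on a held-out tuning split
# ---------------------------------------------------------------------
def grid_search(
    epoch_table, groups, train_ids, condition: str, hemifield: str,
    grid: list[Hyperparams],
    tuning_fraction: float = 0.1,
    spec: NetworkSpec | None = None,
    augment: AugmentConfig | None = None,
    rng_seed: int = 0,
) -> tuple[Hyperparams, list[dict]]:
    """Pick the grid point maximizing tuning-set AUC.

    A `tuning_fraction` of the training subjects (at least one per class)
    is held out from gradient updates; ties break on higher accuracy,
    then grid order.  Divergent cells score AUC 0.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    rng = np.random.default_rng(rng_seed)
    ids = [s for s in train_ids if (s, condition, hemifield) in epoch_table]
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for s in ids:
        by_class[GROUP_LABELS[groups[s]]].append(s)
    tune_ids: list[str] = []
    for cls, members in by_class.items():
        k = max(1, int(round(tuning_fraction * len(members))))
        tune_ids += list(rng.choice(members, size=k, replace=False))
    fit_ids = [s for s in ids if s not in set(tune_ids)]
    tune_labels = np.array([GROUP_LABELS[groups[s]] for s in tune_ids])

    results = []
    best = None
    for i, hp in enumerate(grid):
        try:
            net = train_cell_model(epoch_table, groups, fit_ids, condition,
                                   hemifield, hp, spec=spec, augment=augment,
                                   rng_seed=rng_seed + i)
            probs = predict_subjects(net, epoch_table, tune_ids, condition,
                                     hemifield)
            report = evaluate(probs, tune_labels)
            score = (report.auc, report.accuracy)
        except (RuntimeError, FloatingPointError, ValueError) as err:
            logger.warning("grid cell %d failed (%s); scored as AUC 0",
                           i, err)
            score = (0.0, 0.0)
        results.append({"hyperparams": hp, "auc": score[0],
                        "accuracy": score[1]})
        if best is None or score > best[0]:
            best = (score, hp)
    return best[1], results
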