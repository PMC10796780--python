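"""NIfTI / TSV / JSON persistence for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .epoching import Epoch
from .simulate import BoldRun

__all__ = ["save_run", "load_run", "save_epoch", "load_epoch",
           "save_label_volume", "load_label_volume"]


def _affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    return np.diag([voxel_size_mm] * 3 + [1.0])


def save_run(run: BoldRun, path: str | Path,
             voxel_size_mm: float = 3.0) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), _affine(voxel_size_mm))
    img.header.set_zooms((*[voxel_size_mm] * 3, run.tr_ms / 1000.0))
    img.header["descrip"] = f"{run.subject_id}|{run.group}|{run.space_tag}" \
        .encode()[:80]
    nib.save(img, str(path))


def load_run(path: str | Path) -> BoldRun:
    img = nib.load(str(path))
    desc = img.header["descrip"].tobytes().rstrip(b"\x00").decode()
    subject_id, group, space = (desc.split("|") + ["", "", ""])[:3]
    tr_s = img.header.get_zooms()[3]
    return BoldRun(data=np.asarray(img.dataobj, dtype=float),
                   tr_ms=float(tr_s) * 1000.0, subject_id=subject_id,
                   group=group, space_tag=space or "synthetic-common")


def save_epoch(epoch: Epoch, path: str | Path,
               voxel_size_mm: float = 3.0) -> None:
    """4D NIfTI plus a JSON sidecar carrying epoch metadata."""
    path = Path(path)
    nib.save(nib.Nifti1Image(epoch.data.astype(np.float32),
                             _affine(voxel_size_mm)), str(path))
    sidecar = {
        "condition": epoch.condition,
        "hemifield": epoch.hemifield,
        "lag_times_s": [float(t) for t in epoch.lag_times_s],
        "n_averaged": epoch.n_averaged,
        "normalized": epoch.normalized,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))


def load_epoch(path: str | Path) -> Epoch:
    path = Path(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return Epoch(data=data, lag_times_s=np.array(meta["lag_times_s"]),
                 condition=meta["condition"], hemifield=meta["hemifield"],
                 n_averaged=meta["n_averaged"],
                 normalized=meta["normalized"])


def save_label_volume(labels: np.ndarray, path: str | Path,
                      voxel_size_mm: float = 3.0) -> None:
    nib.save(nib.Nifti1Image(labels.astype(np.int16),
                             _affine(voxel_size_mm)), str(path))


def load_label_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=int)
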