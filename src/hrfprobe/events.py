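"""Event schedules for the event-related speed-discrimination design.

A run presents two stimulus conditions (threshold and sub-maximum speed
contrast) in the left or right visual hemifield.  Each 400 ms stimulation
is followed by a fixation baseline drawn from {4600, 7100, 9600} ms, so
successive onsets are separated by 5000/7500/10000 ms — 2/3/4 TRs at the
2500 ms repetition time, keeping onsets on the TR grid by construction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS", "HEMIFIELDS", "EVENT_DURATION_MS", "BASELINES_MS",
    "generate_event_schedule", "events_to_bids", "events_from_bids",
]

CONDITIONS = ("threshold", "submax")
HEMIFIELDS = ("left", "right")
EVENT_DURATION_MS = 400.0
BASELINES_MS = (4600.0, 7100.0, 9600.0)

#: columns of an event table (onset/duration in ms from run start)
EVENT_COLUMNS = ["onset_ms", "duration_ms", "condition", "hemifield"]


def generate_event_schedule(
    n_reps_per_cell: int = 10,
    rng_seed: int | np.random.Generator = 0,
    start_ms: float = 5000.0,
) -> pd.DataFrame:
    """Randomized event table with `n_reps_per_cell` events per
    condition × hemifield cell.

    Onsets start at `start_ms` (default 2 TRs of lead-in fixation) and are
    spaced by the 400 ms event plus a baseline drawn uniformly from
    {4600, 7100, 9600} ms.  Deterministic under a fixed seed.
    """
    if n_reps_per_cell < 1:
        raise ValueError("n_reps_per_cell must be >= 1")
    rng = np.random.default_rng(rng_seed)
    cells = [(c, h) for c in CONDITIONS for h in HEMIFIELDS
             for _ in range(n_reps_per_cell)]
    order = rng.permutation(len(cells))
    baselines = rng.choice(BASELINES_MS, size=len(cells))
    onsets = start_ms + np.concatenate(
        [[0.0], np.cumsum(EVENT_DURATION_MS + baselines[:-1])])
    rows = [
        (onsets[i], EVENT_DURATION_MS, *cells[order[i]])
        for i in range(len(cells))
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def validate_schedule(events: pd.DataFrame) -> None:
    """Raise if onsets are not strictly increasing or columns missing."""
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    onsets = events["onset_ms"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")


def events_to_bids(events: pd.DataFrame, path: str | Path) -> None:
    """Write a BIDS-style events TSV (onset/duration in seconds,
    trial_type = condition_hemifield)."""
    out = pd.DataFrame({
        "onset": events["onset_ms"] / 1000.0,
        "duration": events["duration_ms"] / 1000.0,
        "trial_type": events["condition"] + "_" + events["hemifield"],
    })
    out.to_csv(path, sep="\t", index=False)


def events_from_bids(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-style events TSV back into the internal table."""
    df = pd.read_csv(path, sep="\t")
    cond_hemi = df["trial_type"].str.rsplit("_", n=1, expand=True)
    return pd.DataFrame({
        "onset_ms": df["onset"] * 1000.0,
        "duration_ms": df["duration"] * 1000.0,
        "condition": cond_hemi[0],
        "hemifield": cond_hemi[1],
    })
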