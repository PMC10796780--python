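"""Descending logarithmic staircase for speed-discrimination thresholds.

The behavioral task finds the smallest speed difference (delta, °/s) a
subject can discriminate.  Starting from the initial target speed minus
the reference speed, delta is decreased after each correct response and
increased after each incorrect one, multiplicatively by the current step
in dB.  A change of adjustment direction is a reversal; the step size
shrinks geometrically from 1 dB toward 0.05 dB across reversals.  The
staircase ends at six reversals (two practice, four experimental) and the
threshold is the arithmetic mean of the deltas at the last four reversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["StaircaseConfig", "StaircaseTrace", "simulate_staircase"]


@dataclass(frozen=True)
class StaircaseConfig:
    initial_speed: float = 24.0      # °/s, initial target speed
    reference_speed: float = 5.0     # °/s
    step_db_start: float = 1.0
    step_db_end: float = 0.05
    n_reversals: int = 6
    n_threshold_reversals: int = 4
    max_trials: int = 500

    @property
    def initial_delta(self) -> float:
        return self.initial_speed - self.reference_speed


@dataclass
class StaircaseTrace:
    trial_deltas: list[float] = field(default_factory=list)
    responses: list[bool] = field(default_factory=list)
    reversal_deltas: list[float] = field(default_factory=list)
    estimated_threshold: float = float("nan")
    truncated: bool = False


def _step_schedule(cfg: StaircaseConfig) -> np.ndarray:
    """dB step in effect before reversal k, geometric from start to end."""
    n = cfg.n_reversals
    if n == 1:
        return np.array([cfg.step_db_start])
    ratio = (cfg.step_db_end / cfg.step_db_start) ** (1.0 / (n - 1))
    return cfg.step_db_start * ratio ** np.arange(n)


def simulate_staircase(
    observer_threshold: float,
    config: StaircaseConfig | None = None,
    rng_seed: int | np.random.Generator = 0,
    lapse_rate: float = 0.0,
    observer: Callable[[float], bool] | None = None,
) -> StaircaseTrace:
    """Run the staircase against a simulated observer.

    The default observer responds correctly iff the current delta is at
    least `observer_threshold` (°/s), with an optional lapse probability
    of answering at random.  If the reversal criterion is not reached
    within ``max_trials``, the trace is truncated (flagged, not raised)
    and the threshold is estimated from the reversals available.
    """
    cfg = config or StaircaseConfig()
    if cfg.initial_delta <= 0:
        raise ValueError("initial delta must be > 0")
    if not np.isfinite(cfg.max_trials) or cfg.max_trials < 1:
        raise ValueError("max_trials must be a finite positive count")
    rng = np.random.default_rng(rng_seed)
    if observer is None:
        def observer(delta: float) -> bool:
            if lapse_rate and rng.random() < lapse_rate:
                return bool(rng.random() < 0.5)
            return delta >= observer_threshold

    steps_db = _step_schedule(cfg)
    trace = StaircaseTrace()
    delta = cfg.initial_delta
    direction = -1  # descending staircase starts by decreasing delta
    for _ in range(cfg.max_trials):
        correct = bool(observer(delta))
        trace.trial_deltas.append(delta)
        trace.responses.append(correct)
        new_direction = -1 if correct else +1
        if new_direction != direction:
            trace.reversal_deltas.append(delta)
            direction = new_direction
            if len(trace.reversal_deltas) >= cfg.n_reversals:
                break
        step = steps_db[min(len(trace.reversal_deltas), cfg.n_reversals - 1)]
        delta *= 10.0 ** (new_direction * step / 20.0)
    else:
        trace.truncated = True

    tail = trace.reversal_deltas[-cfg.n_threshold_reversals:]
    if tail:
        trace.estimated_threshold = float(np.mean(tail))
    return trace
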