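"""Ground-truth hemodynamic response model.

The simulator uses a difference-of-gamma (double-gamma) kernel: a positive
gamma-shaped lobe peaking a few seconds after the event, minus a scaled,
slower gamma lobe producing the post-stimulus undershoot.  The
parameterization exposes interpretable knobs — response gain, time to peak,
undershoot timing/depth, and an overall latency shift — so that
group-level alterations (lower peak, delayed response, attenuated
undershoot) can be injected and later recovered by FIR deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "make_hrf", "GroupHRFOffsets", "apply_offsets"]


@dataclass(frozen=True)
class HRFParams:
    """Parameters of the double-gamma hemodynamic response.

    Attributes
    ----------
    amplitude:
        Dimensionless response gain; the maximum of the positive lobe
        (before undershoot subtraction) equals ``amplitude``.
    time_to_peak:
        Mode of the positive lobe, seconds after the (shifted) event.
    undershoot_delay:
        Mode of the undershoot lobe, seconds.
    peak_dispersion, undershoot_dispersion:
        Gamma scale parameters (seconds) controlling lobe widths.
    undershoot_ratio:
        Depth of the undershoot lobe relative to the positive lobe (>= 0).
    latency_shift:
        Rigid temporal shift of the whole response, seconds; the response
        is identically zero before the shift.
    """

    amplitude: float = 1.0
    time_to_peak: float = 5.0
    undershoot_delay: float = 15.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 0.25
    latency_shift: float = 0.0

    def __post_init__(self) -> None:
        for name in ("time_to_peak", "undershoot_delay",
                     "peak_dispersion", "undershoot_dispersion"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if not np.isfinite(self.undershoot_ratio) or self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be finite and >= 0")
        if not np.isfinite(self.latency_shift):
            raise ValueError("latency_shift must be finite")


def _gamma_lobe(t: np.ndarray, mode: float, dispersion: float) -> np.ndarray:
    """Gamma pdf with its mode at `mode`, normalized to unit maximum."""
    shape = mode / dispersion + 1.0
    pdf = stats.gamma.pdf(t, a=shape, scale=dispersion)
    peak = stats.gamma.pdf(mode, a=shape, scale=dispersion)
    return pdf / peak


def make_hrf(params: HRFParams, sample_times: np.ndarray) -> np.ndarray:
    """Evaluate the double-gamma response at `sample_times` (seconds).

    The positive lobe is scaled so its maximum equals ``params.amplitude``
    before the undershoot lobe is subtracted; the whole kernel is shifted
    right by ``latency_shift`` and is zero before it.
    """
    t = np.asarray(sample_times, dtype=float)
    if t.ndim != 1:
        raise ValueError("sample_times must be 1-D")
    if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
        raise ValueError("sample_times must be nonnegative and sorted")
    if params.amplitude == 0:
        return np.zeros_like(t)
    ts = t - params.latency_shift
    out = np.zeros_like(ts)
    pos = ts > 0
    out[pos] = _gamma_lobe(ts[pos], params.time_to_peak,
                           params.peak_dispersion)
    out[pos] -= params.undershoot_ratio * _gamma_lobe(
        ts[pos], params.undershoot_delay, params.undershoot_dispersion)
    return params.amplitude * out


@dataclass(frozen=True)
class GroupHRFOffsets:
    """Multiplicative/additive alterations applied to a group's HRF.

    Defaults reflect the patient-group phenomena the pipeline is built to
    detect: a lower peak, a delayed response, and a less pronounced
    undershoot.
    """

    amplitude_ratio: float = 0.7
    latency_shift_s: float = 2.5
    undershoot_ratio_scale: float = 0.4


def apply_offsets(params: HRFParams, offsets: GroupHRFOffsets) -> HRFParams:
    return replace(
        params,
        amplitude=params.amplitude * offsets.amplitude_ratio,
        latency_shift=params.latency_shift + offsets.latency_shift_s,
        undershoot_ratio=params.undershoot_ratio * offsets.undershoot_ratio_scale,
    )
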