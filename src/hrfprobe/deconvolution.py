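"""FIR-deconvolution GLM estimation of the hemodynamic response in ROIs.

Instead of assuming an HRF shape, each event type gets one 0/1 stick
regressor per post-stimulus lag covering 20 s (8 lags at TR 2.5 s); the
ordinary-least-squares beta series reconstructs the full BOLD response.
Event types default to the four condition × hemifield cells.  Shape
features (peak amplitude, time to peak, undershoot depth) quantify group
differences in the reconstructed responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import BoldRun, onset_to_index

logger = logging.getLogger(__name__)

__all__ = [
    "FIRDesign", "HRFEstimate", "HRFFeatures", "SingularDesignError",
    "roi_timecourse", "build_fir_design", "fit_fir", "group_hrf_summary",
    "hrf_features",
]


class SingularDesignError(np.linalg.LinAlgError):
    pass


@dataclass
class FIRDesign:
    matrix: np.ndarray              # (n_volumes, n_columns)
    event_types: list[str]
    n_lags: int
    lag_times_s: np.ndarray
    column_names: list[str]


@dataclass
class HRFEstimate:
    """Per-ROI FIR betas, one response series per event type."""

    betas: pd.DataFrame             # columns: event_type, lag_s, beta, se
    roi_id: int
    subject_id: str
    group: str


@dataclass(frozen=True)
class HRFFeatures:
    peak_amplitude: float
    time_to_peak_s: float                 # raw lag time of the peak
    time_to_peak_interp_s: float          # parabolic 3-point refinement
    undershoot_depth: float               # >= 0
    returns_to_baseline: bool


def roi_timecourse(run: BoldRun, mask: np.ndarray) -> np.ndarray:
    """Per-volume mean over the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.data.shape[:3]:
        raise ValueError("mask shape does not match run volume shape")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return run.data[mask].mean(axis=0)


def build_fir_design(
    events: pd.DataFrame,
    tr_ms: float,
    n_volumes: int,
    coverage_s: float = 20.0,
    event_type_cols: tuple[str, ...] = ("condition", "hemifield"),
    linear_drift: bool = False,
) -> FIRDesign:
    """Stick-predictor design matrix with an intercept.

    Events whose lag columns run past the end of the run keep their
    truncated support (OLS handles partial columns); a note is logged.
    """
    if coverage_s <= 0:
        raise ValueError("coverage_s must be > 0")
    n_lags = int(np.ceil(coverage_s * 1000.0 / tr_ms))
    etypes = sorted(
        events[list(event_type_cols)].astype(str).agg("_".join, axis=1)
        .unique())
    cols = {}
    for et in etypes:
        for lag in range(n_lags):
            cols[f"{et}_lag{lag}"] = np.zeros(n_volumes)
    keys = events[list(event_type_cols)].astype(str).agg("_".join, axis=1)
    truncated = 0
    for key, onset in zip(keys, events["onset_ms"]):
        idx = onset_to_index(onset, tr_ms)
        if idx + n_lags > n_volumes:
            truncated += 1
        for lag in range(n_lags):
            if 0 <= idx + lag < n_volumes:
                cols[f"{key}_lag{lag}"][idx + lag] += 1.0
    if truncated:
        logger.info("%d event(s) within coverage of the run end; their "
                    "truncated lag columns are retained", truncated)

    names = ["intercept"] + list(cols)
    matrix = [np.ones(n_volumes)] + list(cols.values())
    if linear_drift:
        names.append("drift")
        matrix.append(np.linspace(-0.5, 0.5, n_volumes))
    X = np.column_stack(matrix)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify (nearly) dependent columns from the R factor of a QR
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise SingularDesignError(
            f"rank-deficient FIR design; collinear columns: {bad}")
    tr_s = tr_ms / 1000.0
    return FIRDesign(matrix=X, event_types=etypes, n_lags=n_lags,
                     lag_times_s=np.arange(n_lags) * tr_s,
                     column_names=names)


def fit_fir(design: FIRDesign, series: np.ndarray,
            roi_id: int = 0, subject_id: str = "", group: str = "",
) -> HRFEstimate:
    """OLS betas and standard errors for one ROI time course."""
    y = np.asarray(series, float)
    X = design.matrix
    n, p = X.shape
    if len(y) != n:
        raise ValueError("series length does not match the design")
    if n <= p:
        raise ValueError("need more volumes than design columns")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise SingularDesignError("singular normal equations") from err
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))

    rows = []
    for et in design.event_types:
        for lag in range(design.n_lags):
            j = design.column_names.index(f"{et}_lag{lag}")
            rows.append((et, design.lag_times_s[lag], beta[j], se[j]))
    table = pd.DataFrame(rows, columns=["event_type", "lag_s", "beta", "se"])
    return HRFEstimate(betas=table, roi_id=roi_id, subject_id=subject_id,
                       group=group)


def group_hrf_summary(estimates: list[HRFEstimate]) -> pd.DataFrame:
    """Per-lag mean and SD across subjects, by group × event type × ROI."""
    if not estimates:
        raise ValueError("no estimates to summarize")
    frames = []
    for est in estimates:
        df = est.betas.copy()
        df["group"] = est.group
        df["roi_id"] = est.roi_id
        df["subject_id"] = est.subject_id
        frames.append(df)
    longf = pd.concat(frames, ignore_index=True)
    counts = longf.groupby(["group", "roi_id", "event_type"])[
        "subject_id"].nunique()
    if counts.min() < 2:
        raise ValueError("need >= 2 estimates per group for a summary")
    out = (longf.groupby(["group", "roi_id", "event_type", "lag_s"])["beta"]
           .agg(mean="mean", sd="std", n="count").reset_index())
    return out


def hrf_features(betas: np.ndarray, tr_s: float,
                 peak_search_from_lag: int = 1) -> HRFFeatures:
    """Shape features of one reconstructed response (beta series).

    The peak search starts at lag 1 to avoid onset-volume artifacts;
    ``time_to_peak_interp_s`` refines the raw lag time by parabolic
    interpolation over the peak's 3-point neighborhood.  The undershoot
    is the deepest negative excursion after the peak.
    """
    b = np.asarray(betas, float)
    if b.ndim != 1 or len(b) < 4:
        raise ValueError("need a 1-D beta series with >= 4 lags")
    if np.ptp(b) < 1e-15:
        raise ValueError("features undefined for an all-equal beta series")
    k0 = peak_search_from_lag
    peak_lag = k0 + int(np.argmax(b[k0:]))
    peak_amp = float(b[peak_lag])
    t_peak = peak_lag * tr_s
    if 0 < peak_lag < len(b) - 1:
        left, mid, right = b[peak_lag - 1:peak_lag + 2]
        denom = left - 2 * mid + right
        offset = 0.5 * (left - right) / denom if abs(denom) > 1e-15 else 0.0
        t_interp = (peak_lag + float(np.clip(offset, -0.5, 0.5))) * tr_s
    else:
        t_interp = t_peak
    after = b[peak_lag + 1:]
    undershoot = float(max(0.0, -after.min())) if after.size else 0.0
    returns = bool(abs(b[-1]) <= 0.2 * abs(peak_amp)) if peak_amp else False
    return HRFFeatures(peak_amplitude=peak_amp, time_to_peak_s=t_peak,
                       time_to_peak_interp_s=t_interp,
                       undershoot_depth=undershoot,
                       returns_to_baseline=returns)
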