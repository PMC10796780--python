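"""Plots of group-mean HRFs reconstructed by FIR deconvolution."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_group_hrf"]

_GROUP_COLORS = {"control": "tab:blue", "patient": "tab:red"}


def plot_group_hrf(summary, out_path: str | Path,
                   roi_id: int | None = None) -> Path:
    """One panel per (ROI, event type): group mean beta series ± SD.

    `summary` is the long-format table from
    :func:`hrfprobe.deconvolution.group_hrf_summary`.
    """
    sub = summary if roi_id is None else summary[summary["roi_id"] == roi_id]
    if not len(sub):
        raise ValueError("nothing to plot for the requested ROI")
    panels = sorted({(r, e) for r, e in
                     zip(sub["roi_id"], sub["event_type"])})
    ncols = min(4, len(panels))
    nrows = (len(panels) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, squeeze=False, sharex=True,
                             figsize=(3.2 * ncols, 2.6 * nrows))
    for ax, (roi, etype) in zip(axes.ravel(), panels):
        for group, block in sub[(sub["roi_id"] == roi)
                                & (sub["event_type"] == etype)].groupby(
                                    "group"):
            block = block.sort_values("lag_s")
            color = _GROUP_COLORS.get(group)
            ax.plot(block["lag_s"], block["mean"], label=group, color=color)
            ax.fill_between(block["lag_s"],
                            block["mean"] - block["sd"],
                            block["mean"] + block["sd"],
                            alpha=0.2, color=color)
        ax.axhline(0.0, lw=0.5, color="gray")
        ax.set_title(f"ROI {roi} · {etype}", fontsize=9)
        ax.set_xlabel("time after onset (s)")
    axes[0, 0].set_ylabel("beta (signal units)")
    axes[0, 0].legend(fontsize=8)
    for ax in axes.ravel()[len(panels):]:
        ax.set_visible(False)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
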