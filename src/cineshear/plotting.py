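"""Summary figures for sweep results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_flow_waveforms", "plot_resolution_scatter", "plot_quarter_summary"]


def plot_flow_waveforms(waveforms, labels, path, reference=None):
    """Overlay flow waveforms (one line per measurement)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for wf, label in zip(waveforms, labels):
        ax.plot(wf.frame_times, wf.q, "--", label=label)
    if reference is not None:
        ax.plot(reference.frame_times, reference.q, "r-", lw=2, label="reference")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("flow [mL/s]")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_resolution_scatter(records, path):
    """Hemodynamic parameters vs spatial and temporal resolution."""
    responses = [
        ("mean_flow", "mean flow [mL/s]"),
        ("peak_flow", "peak flow [mL/s]"),
        ("mean_wss", "WSS [Pa]"),
        ("mean_osi", "OSI"),
    ]
    fig, axes = plt.subplots(len(responses), 2, figsize=(8, 3 * len(responses)))
    sr = np.array([r.spatial_resolution for r in records])
    tr = np.array([r.temporal_resolution for r in records])
    for i, (attr, label) in enumerate(responses):
        y = np.array([getattr(r, attr) for r in records])
        for j, (x, xlabel) in enumerate([(sr, "spatial resolution [mm]"), (tr, "temporal resolution [ms]")]):
            ax = axes[i, j]
            ax.plot(x, y, "ko", ms=4)
            coef = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, np.polyval(coef, xs), "b-", lw=1)
            ax.set_xlabel(xlabel)
            ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_quarter_summary(summaries, titles, path, quantity="wss"):
    """2x2 heat tiles of per-quarter means for a few measurements."""
    n = len(summaries)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.5))
    if n == 1:
        axes = [axes]
    for ax, summary, title in zip(axes, summaries, titles):
        sector = getattr(summary, quantity)
        # sector order: TL, TR, BL, BR -> image layout
        tiles = np.array([[sector.means[0], sector.means[1]], [sector.means[2], sector.means[3]]])
        im = ax.imshow(tiles, cmap="viridis")
        for (r, c), val in np.ndenumerate(tiles):
            ax.text(c, r, f"{val:.2f}", ha="center", va="center", color="w", fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(title, fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
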