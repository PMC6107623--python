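"""Small matplotlib helpers for traces, segmentations and kymographs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kymograph import Kymograph

_STAGE_COLOURS = {
    "induction": "#cccccc",
    "initial": "#ffd8a8",
    "main": "#b2f2bb",
    "late": "#a5d8ff",
    "exhausted": "#e9ecef",
}


def plot_trace_analysis(result, path: str | Path) -> None:
    """Raw + corrected trace with detected peaks/troughs and stage shading."""
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    t = result.trace.time_s / 60.0
    ax0.plot(t, result.trace.raw, lw=0.6, color="k", label="raw")
    if result.trace.baseline is not None:
        ax0.plot(t, result.trace.baseline, lw=0.8, color="tab:orange", label="baseline")
    ax0.set_ylabel("intensity")
    ax0.legend(loc="upper right", fontsize=8)

    corrected = result.trace.corrected
    ax1.plot(t, corrected, lw=0.6, color="k")
    ax1.plot(result.peaks.peak_times / 60.0, result.peaks.peak_values, "r.", ms=4)
    ax1.plot(result.peaks.trough_times / 60.0, result.peaks.trough_values, "b.", ms=4)
    for iv in result.segmentation.intervals:
        ax1.axvspan(
            iv.start_s / 60.0, iv.end_s / 60.0,
            color=_STAGE_COLOURS.get(iv.label, "#ffffff"), alpha=0.4, lw=0,
        )
    ax1.set_xlabel("time from mixing (min)")
    ax1.set_ylabel("corrected")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_kymograph(kymo: Kymograph, path: str | Path, tracks=None) -> None:
    """Kymograph image (time on x, slot position on y), optional track overlay."""
    fig, ax = plt.subplots(figsize=(10, 4))
    extent = (
        float(kymo.timestamps[0]) / 60.0,
        float(kymo.timestamps[-1]) / 60.0,
        kymo.length_px,
        0,
    )
    ax.imshow(kymo.collapsed(), aspect="auto", cmap="Blues", extent=extent)
    for tr in tracks or []:
        ax.plot(np.asarray(tr.times_s) / 60.0, tr.positions_px, lw=1.0, color="red")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("position along slot (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
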