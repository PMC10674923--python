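"""Plotting helpers for processed recordings and interval predictions."""

from __future__ import annotations

import numpy as np

from .io import ExertionIntervals
from .pipeline import ProcessedRecording


def plot_intervals(processed: ProcessedRecording, channel: str = "ch3",
                   truth: ExertionIntervals | None = None,
                   predicted: ExertionIntervals | None = None, ax=None):
    """Plot one processed channel with true (solid) and predicted (dashed)
    exertion intervals overlaid, in the style used to inspect detections."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    series = processed.signals[channel]
    t = np.arange(series.size) / processed.fs
    ax.plot(t, series, lw=0.6, color="k", label=channel)
    top = float(np.max(series)) if series.size else 1.0
    if truth is not None:
        for i, (s, e) in enumerate(truth):
            ax.axvspan(s / processed.fs, e / processed.fs, color="tab:blue", alpha=0.15,
                       label="true label" if i == 0 else None)
    if predicted is not None:
        for i, (s, e) in enumerate(predicted):
            ax.plot([s / processed.fs, e / processed.fs], [1.05 * top] * 2,
                    color="magenta", ls="--", lw=2,
                    label="predicted label" if i == 0 else None)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(channel)
    ax.legend(loc="upper right", fontsize=8)
    return ax
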