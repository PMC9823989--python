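"""Plotting helpers for hypnograms and recognizer curves."""

from __future__ import annotations

import numpy as np

from .datatypes import Hypnogram

#: Vertical ordering used on hypnogram plots (wake on top, deep at bottom).
_STAGE_Y = {"W": 3, "R": 2, "L": 1, "D": 0}


def plot_hypnogram(hyp: Hypnogram, ax=None, **step_kwargs):
    """Step plot of a hypnogram with the conventional stage ordering."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    hours = np.arange(len(hyp)) * hyp.epoch_len / 3600.0
    y = np.array([_STAGE_Y[s] for s in hyp.labels])
    ax.step(hours, y, where="post", **step_kwargs)
    ax.set_yticks(sorted(_STAGE_Y.values()))
    ax.set_yticklabels([s for s, _ in sorted(_STAGE_Y.items(), key=lambda kv: kv[1])])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("stage")
    return ax


def plot_recognizer_curves(curves: dict, rec, ax=None):
    """F1/SF1/BF1 and the recognizer threshold(s) for one night."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    n = curves["F1"].size
    x = np.arange(n) * 30.0 / 3600.0
    ax.plot(x, curves["F1"], lw=0.5, alpha=0.4, label="F1")
    ax.plot(x, curves["SF1"], lw=1.2, label="SF1")
    ax.plot(x, curves["BF1"], lw=1.2, label="BF1")
    if rec.direction == "band":
        ax.plot(x, curves["BF1"] + rec.k, "--", lw=0.8, label="BF1+k1")
        ax.plot(x, curves["BF1"] + (rec.k2 or -rec.k), "--", lw=0.8, label="BF1+k2")
    else:
        ax.plot(x, curves["BF1"] + rec.k, "--", lw=0.8, label="BF1+k")
    ax.set_xlabel("time (h)")
    ax.set_title(f"{rec.stage} recognizer")
    ax.legend(loc="upper right", fontsize=8)
    return ax
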