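"""Minimal QC plots for curve sets and predictions."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .curves import CurveSet
from .design import ATTRIBUTES


def plot_curve_set(curve_set: CurveSet, ax=None, top_k: int = 6):
    """TDS dominance proportions (top-k attributes) and TL curve on twin axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    pts = curve_set.grid.points
    order = np.argsort(curve_set.tds.proportions.max(axis=1))[::-1][:top_k]
    for i in order:
        ax.plot(pts, curve_set.tds.proportions[i], label=ATTRIBUTES[i])
    ax.set_xlabel("normalized time")
    ax.set_ylabel("dominance proportion")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    ax2 = ax.twinx()
    ax2.plot(pts, curve_set.tl.liking, "k--", lw=2, label="TL")
    ax2.set_ylabel("liking (0-9)")
    ax2.set_ylim(0, 9)
    ax.set_title(f"{curve_set.condition_id} ({curve_set.provenance})")
    return ax


def plot_prediction(observed: CurveSet, predicted: np.ndarray, ax=None):
    """Observed vs predicted TL curve for one held-out replicate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    pts = observed.grid.points
    ax.plot(pts, observed.tl.liking, "k-", label="observed TL")
    ax.plot(pts, np.asarray(predicted).ravel(), "r--", label="predicted TL")
    ax.set_xlabel("normalized time")
    ax.set_ylabel("liking")
    ax.set_ylim(0, 9)
    ax.legend()
    ax.set_title(observed.condition_id)
    return ax
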