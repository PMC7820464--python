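"""Simple static plots: raster, synchronization matrix, latency map."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import SpikeTrainSet
from .geometry import ArrayLayout
from .stimulus import LatencyMap
from .synchrony import SyncMatrix


def plot_raster(train_set: SpikeTrainSet, path: Optional[str] = None, ax=None):
    """Electrode raster plot, one row per channel."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for row, eid in enumerate(train_set.channel_ids):
        t = train_set.trains[eid]
        ax.vlines(t, row + 0.6, row + 1.4, lw=0.5, color="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    ax.set_xlim(0, train_set.duration)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_sync_matrix(matrix: SyncMatrix, path: Optional[str] = None, ax=None):
    """Color-mapped electrode-pair synchronization scores (0 to 1)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.scores, vmin=0, vmax=1, cmap="jet")
    ax.figure.colorbar(im, ax=ax, label="synchronization score")
    ax.set_xlabel("electrode")
    ax.set_ylabel("electrode")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_latency_map(latency_map: LatencyMap, layout: ArrayLayout,
                     path: Optional[str] = None, ax=None):
    """Top-down (x, y) electrode map colored by evoked latency (ms)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    xs, ys, cs = [], [], []
    silent_x, silent_y = [], []
    for eid in layout.electrode_ids:
        x, y, _ = layout.electrode(eid).position
        lat = latency_map.mean_latency.get(eid, float("nan"))
        if np.isfinite(lat):
            xs.append(x), ys.append(y), cs.append(lat)
        else:
            silent_x.append(x), silent_y.append(y)
    sc = ax.scatter(xs, ys, c=cs, cmap="viridis", s=60)
    ax.scatter(silent_x, silent_y, c="k", s=30, label="no signal")
    ax.figure.colorbar(sc, ax=ax, label="latency (ms)")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
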