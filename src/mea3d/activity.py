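"""Per-electrode activity metrics: firing rate, active electrodes, bursts.

Bursts follow the ISI-threshold rule used for these recordings: maximal
runs of consecutive spikes whose inter-spike intervals are all at most
0.1 s, kept when the run holds at least 3 spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import SpikeTrainSet

__all__ = [
    "BurstParams",
    "Burst",
    "mean_spike_rate",
    "active_electrodes",
    "detect_bursts",
    "burst_statistics",
    "metrics_table",
]


@dataclass
class BurstParams:
    isi_threshold: float = 0.1          # s
    min_spikes_per_burst: int = 3
    active_electrode_min_spikes: int = 5

    def __post_init__(self) -> None:
        if self.isi_threshold <= 0:
            raise ValueError("ISI threshold must be positive")
        if self.min_spikes_per_burst < 2:
            raise ValueError("a burst needs at least 2 spikes")


@dataclass(frozen=True)
class Burst:
    start: float    # s, first spike of the run
    end: float      # s, last spike of the run
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def mean_spike_rate(train: np.ndarray, duration: float) -> float:
    """Spike count over duration, in Hz."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return np.asarray(train).size / duration


def active_electrodes(train_set: SpikeTrainSet,
                      params: Optional[BurstParams] = None) -> int:
    """Number of electrodes with at least the minimum spike count."""
    params = params or BurstParams()
    return sum(
        1 for t in train_set.trains.values()
        if t.size >= params.active_electrode_min_spikes
    )


def detect_bursts(train: np.ndarray,
                  params: Optional[BurstParams] = None) -> List[Burst]:
    """Maximal short-ISI runs with at least ``min_spikes_per_burst`` spikes."""
    params = params or BurstParams()
    t = np.asarray(train, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("train must be sorted")
    bursts: List[Burst] = []
    if t.size < params.min_spikes_per_burst:
        return bursts
    short = np.diff(t) <= params.isi_threshold
    run_start = 0
    for i in range(len(short) + 1):
        if i == len(short) or not short[i]:
            n = i - run_start + 1
            if n >= params.min_spikes_per_burst:
                bursts.append(Burst(start=t[run_start], end=t[i], n_spikes=n))
            run_start = i + 1
    return bursts


def burst_statistics(bursts: List[Burst], train: np.ndarray,
                     duration: float) -> Dict[str, float]:
    """Summary of the burst structure of one train.

    IBI is end-to-next-start; with fewer than two bursts it is NaN
    (undefined, not an error).  With zero bursts the rate and percentage
    are 0 and the remaining means NaN.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_total = np.asarray(train).size
    n_bursts = len(bursts)
    stats: Dict[str, float] = {
        "n_bursts": float(n_bursts),
        "burst_rate": n_bursts / duration,
        "mean_duration": float("nan"),
        "mean_spikes_per_burst": float("nan"),
        "mean_intraburst_isi": float("nan"),
        "mean_ibi": float("nan"),
        "pct_burst_spikes": 0.0,
    }
    if n_bursts == 0:
        return stats
    durations = np.array([b.duration for b in bursts])
    counts = np.array([b.n_spikes for b in bursts])
    stats["mean_duration"] = float(durations.mean())
    stats["mean_spikes_per_burst"] = float(counts.mean())
    with np.errstate(invalid="ignore"):
        intra = durations / (counts - 1)
    stats["mean_intraburst_isi"] = float(intra.mean())
    if n_bursts >= 2:
        starts = np.array([b.start for b in bursts])
        ends = np.array([b.end for b in bursts])
        stats["mean_ibi"] = float(np.mean(starts[1:] - ends[:-1]))
    if n_total:
        stats["pct_burst_spikes"] = float(100.0 * counts.sum() / n_total)
    return stats


def metrics_table(train_set: SpikeTrainSet,
                  params: Optional[BurstParams] = None,
                  label: Optional[Dict[str, object]] = None) -> pd.DataFrame:
    """Long-format (electrode, metric, value) table of all activity metrics."""
    params = params or BurstParams()
    rows = []
    extra = label or {}
    for eid in train_set.channel_ids:
        t = train_set.trains[eid]
        bursts = detect_bursts(t, params)
        stats = burst_statistics(bursts, t, train_set.duration)
        stats["mean_spike_rate"] = mean_spike_rate(t, train_set.duration)
        for metric, value in stats.items():
            rows.append({"electrode": eid, "metric": metric, "value": value, **extra})
    return pd.DataFrame(rows)
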