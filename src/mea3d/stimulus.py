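"""Optogenetic stimulation-response analysis.

Quantifies light-evoked activity against the pulse protocol: per-trial
on/off firing rates, unpaired two-tailed t-tests across the six trials,
per-shank z-averaged rate-increase maps, and per-electrode synaptic
latency (first spike after each onset, artifact-blanked, averaged over
responding trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpikeTrainSet, StimProtocol
from .geometry import ArrayLayout

__all__ = [
    "LatencyParams",
    "LatencyMap",
    "epoch_rates",
    "compare_on_off",
    "rate_increase_map",
    "estimate_latency",
]


@dataclass
class LatencyParams:
    """Evoked-latency estimation rule.

    The first ``artifact_blank`` milliseconds after each onset are ignored
    (photovoltaic stimulation artifact); a response is the first spike in
    the remaining ``response_window``; per-electrode latency is the mean
    over trials with a response.
    """

    artifact_blank: float = 1.0      # ms
    response_window: float = 50.0    # ms

    def __post_init__(self) -> None:
        if not 0 <= self.artifact_blank < self.response_window:
            raise ValueError("blanking must be shorter than the response window")


@dataclass
class LatencyMap:
    """Per-electrode evoked latencies (ms); NaN marks no-response."""

    mean_latency: Dict[int, float]
    trial_latencies: Dict[int, np.ndarray]
    n_responding: Dict[int, int] = field(default_factory=dict)

    def defined(self) -> Dict[int, float]:
        return {e: v for e, v in self.mean_latency.items() if np.isfinite(v)}


def epoch_rates(trains: SpikeTrainSet, protocol: StimProtocol
                ) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    """Per-electrode, per-trial (rate_on, rate_off) in Hz.

    Spikes are counted in each on-interval and the immediately following
    off-interval (the rest of the stimulation period).
    """
    if protocol.end > trains.duration + 1e-9:
        raise ValueError("stimulation trials extend past the recording")
    onsets, offsets = protocol.onsets, protocol.offsets
    off_len = protocol.period - protocol.pulse_width
    out: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for eid in trains.channel_ids:
        t = trains.trains[eid]
        n_on = np.searchsorted(t, offsets) - np.searchsorted(t, onsets)
        n_off = np.searchsorted(t, offsets + off_len) - np.searchsorted(t, offsets)
        out[eid] = (n_on / protocol.pulse_width, n_off / off_len)
    return out


def compare_on_off(rates_on: np.ndarray, rates_off: np.ndarray
                   ) -> Tuple[float, float]:
    """Two-tailed unpaired t-test between per-trial on and off rates.

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    with zero variance give (inf-signed t, 0).
    """
    a = np.asarray(rates_on, dtype=float)
    b = np.asarray(rates_off, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per condition")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def rate_increase_map(rates: Dict[int, Tuple[np.ndarray, np.ndarray]],
                      layout: ArrayLayout) -> pd.DataFrame:
    """Per-shank z-averaged on-minus-off firing-rate increase (Hz).

    Electrodes with no spikes in either condition are flagged ``no_signal``
    and excluded from their shank's average (an all-silent shank averages
    to NaN, rendered black in the maps).
    """
    rows = []
    for eid, (on, off) in rates.items():
        e = layout.electrode(eid)
        silent = bool(on.sum() == 0 and off.sum() == 0)
        rows.append({
            "electrode": eid,
            "shank": e.shank_index,
            "x": e.position[0],
            "y": e.position[1],
            "delta_rate": float(on.mean() - off.mean()),
            "no_signal": silent,
        })
    df = pd.DataFrame(rows)
    shank = (
        df[~df.no_signal]
        .groupby("shank")["delta_rate"]
        .mean()
        .reindex([s.index for s in layout.shanks])
    )
    df = df.merge(shank.rename("shank_delta_rate"), left_on="shank",
                  right_index=True, how="left")
    return df


def estimate_latency(trains: SpikeTrainSet, protocol: StimProtocol,
                     params: Optional[LatencyParams] = None) -> LatencyMap:
    """First-spike latency relative to each LED onset, mean over trials.

    For each trial and electrode the response is the first spike in
    ``(onset + blank, onset + window]``; its time minus the onset is the
    trial latency.  Electrodes with no responding trial are undefined
    (NaN) and excluded from maps and fits.
    """
    params = params or LatencyParams()
    if protocol.onsets[-1] + params.response_window * 1e-3 > trains.duration:
        raise ValueError("response window extends past the recording")
    blank_s = params.artifact_blank * 1e-3
    window_s = params.response_window * 1e-3
    mean_latency: Dict[int, float] = {}
    trial_latencies: Dict[int, np.ndarray] = {}
    n_responding: Dict[int, int] = {}
    for eid in trains.channel_ids:
        t = trains.trains[eid]
        lat = np.full(protocol.n_trials, np.nan)
        for k, onset in enumerate(protocol.onsets):
            i = np.searchsorted(t, onset + blank_s, side="right")
            if i < t.size and t[i] <= onset + window_s:
                lat[k] = (t[i] - onset) * 1e3
        trial_latencies[eid] = lat
        good = np.isfinite(lat)
        n_responding[eid] = int(good.sum())
        mean_latency[eid] = float(lat[good].mean()) if good.any() else float("nan")
    return LatencyMap(mean_latency=mean_latency, trial_latencies=trial_latencies,
                      n_responding=n_responding)
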