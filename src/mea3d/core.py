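"""Core containers shared across the analysis stages.

Unit conventions (enforced throughout the package):

* spike times and recording durations in **seconds** (float64),
* spatial coordinates in **micrometres**, distances handed to the velocity
  regression in **millimetres**,
* synaptic / conduction delays in **milliseconds**,
* voltages in **microvolts**.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Iterator, Optional

import numpy as np

__all__ = ["SpikeTrainSet", "StimProtocol", "RawTraceSet"]


@dataclass
class SpikeTrainSet:
    """Per-channel sorted spike times.

    ``trains`` maps an integer channel id (electrode or neuron id) to a
    sorted float64 array of spike times in seconds within ``[0, duration]``.
    ``amplitudes`` optionally carries one peak amplitude (μV) per spike,
    aligned with ``trains``.
    """

    trains: Dict[int, np.ndarray]
    duration: float
    meta: Dict[str, Any] = field(default_factory=dict)
    amplitudes: Optional[Dict[int, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        clean = {}
        for key, t in self.trains.items():
            arr = np.asarray(t, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"train {key} is not one-dimensional")
            if arr.size and (arr.min() < 0 or arr.max() > self.duration):
                raise ValueError(f"train {key} has times outside [0, duration]")
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"train {key} is not strictly increasing")
            clean[int(key)] = arr
        self.trains = clean

    def __getitem__(self, key: int) -> np.ndarray:
        return self.trains[key]

    def __iter__(self) -> Iterator[int]:
        return iter(self.trains)

    def __len__(self) -> int:
        return len(self.trains)

    @property
    def channel_ids(self) -> list[int]:
        return sorted(self.trains)

    def n_spikes(self, key: Optional[int] = None) -> int:
        if key is not None:
            return int(self.trains[key].size)
        return int(sum(t.size for t in self.trains.values()))

    def subset(self, keys) -> "SpikeTrainSet":
        keys = [int(k) for k in keys]
        amps = None
        if self.amplitudes is not None:
            amps = {k: self.amplitudes[k] for k in keys if k in self.amplitudes}
        return SpikeTrainSet(
            trains={k: self.trains[k] for k in keys},
            duration=self.duration,
            meta=dict(self.meta),
            amplitudes=amps,
        )


@dataclass
class StimProtocol:
    """Periodic LED pulse protocol.

    Defaults follow the stimulation settings used throughout the evoked
    analyses: 0.2 Hz pulse trains, 2.5 s pulses (50 % duty cycle), six
    stimulation trials per session.
    """

    frequency: float = 0.2          # Hz
    pulse_width: float = 2.5        # s
    n_trials: int = 6
    start: float = 1.0              # s, first onset

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.pulse_width <= 0 or self.n_trials < 1:
            raise ValueError("invalid stimulation protocol")
        if self.pulse_width > self.period:
            raise ValueError("pulse width exceeds stimulation period")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def duty(self) -> float:
        return self.pulse_width / self.period

    @property
    def onsets(self) -> np.ndarray:
        return self.start + self.period * np.arange(self.n_trials)

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.pulse_width

    @property
    def end(self) -> float:
        """Time at which the last off-interval closes."""
        return float(self.onsets[-1] + self.period)


@dataclass
class RawTraceSet:
    """Per-electrode sampled extracellular voltage (μV) at a fixed rate."""

    traces: Dict[int, np.ndarray]
    sample_rate: float = 20_000.0   # S/s
    meta: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        n = {len(t) for t in self.traces.values()}
        if len(n) > 1:
            raise ValueError("all traces must have equal length")

    @property
    def n_samples(self) -> int:
        if not self.traces:
            return 0
        return len(next(iter(self.traces.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def channel_ids(self) -> list[int]:
        return sorted(self.traces)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate
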