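"""Synaptic transmission velocity from distance-versus-latency regression.

The slope of the ordinary-least-squares fit of stimulation-site distance
(mm, response variable — following the analysis' axis convention) on evoked
latency (s, predictor) is the transmission velocity in mm/s.  Fits are
reported overall and stratified into longitudinal (along the
soma-neurite-soma axis) and transverse (across it) electrode subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy import stats

from .geometry import ArrayLayout
from .stimulus import LatencyMap

__all__ = [
    "VelocityFit",
    "electrode_distances",
    "classify_direction",
    "fit_velocity",
    "compare_velocities",
    "velocity_table",
]


@dataclass
class VelocityFit:
    slope: float                 # mm/s
    intercept: float             # mm
    ci_low: float                # mm/s, 95 % CI on the slope
    ci_high: float
    stderr: float                # mm/s
    n: int
    direction: str = "all"
    r_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.n >= 3 and not (self.ci_low - 1e-9 <= self.slope <= self.ci_high + 1e-9):
            raise ValueError("confidence interval must contain the slope")

    def contains(self, velocity: float) -> bool:
        return self.ci_low <= velocity <= self.ci_high


def electrode_distances(layout: ArrayLayout, stim_electrode: int
                        ) -> Dict[int, float]:
    """Euclidean 3D distance (mm) from the stimulation electrode to all."""
    stim = np.array(layout.electrode(stim_electrode).position)
    return {
        eid: float(np.linalg.norm(np.array(layout.electrode(eid).position) - stim) / 1000.0)
        for eid in layout.electrode_ids
    }


def classify_direction(layout: ArrayLayout, stim_electrode: int,
                       tolerance: Optional[float] = None) -> Dict[int, str]:
    """Label electrodes longitudinal / transverse / other w.r.t. the
    stimulation site.

    Longitudinal: same row (|Δy| within tolerance) but a different column;
    transverse: same column but a different row; everything else (including
    the stimulation shank itself) is ``other``.  Default tolerance is half
    the smaller array pitch, since exact y = 0 / x = 0 planes never hold
    off-grid.
    """
    if tolerance is None:
        tolerance = min(layout.row_pitch, layout.column_pitch) / 2.0
    stim = np.array(layout.electrode(stim_electrode).position)
    labels: Dict[int, str] = {}
    for eid in layout.electrode_ids:
        d = np.array(layout.electrode(eid).position) - stim
        dx, dy = abs(d[0]), abs(d[1])
        if dy <= tolerance and dx > tolerance:
            labels[eid] = "longitudinal"
        elif dx <= tolerance and dy > tolerance:
            labels[eid] = "transverse"
        else:
            labels[eid] = "other"
    return labels


def fit_velocity(latencies_ms: Dict[int, float], distances_mm: Dict[int, float],
                 subset: Optional[Iterable[int]] = None,
                 direction: str = "all") -> VelocityFit:
    """OLS of distance (mm) on latency (s); slope is velocity in mm/s.

    Requires at least 3 electrodes with a defined latency; the 95 % CI uses
    the slope's standard error with the t quantile at n - 2 degrees of
    freedom.
    """
    keys = [k for k in (subset if subset is not None else latencies_ms)
            if k in latencies_ms and np.isfinite(latencies_ms[k])]
    if len(keys) < 3:
        raise ValueError(f"need >= 3 responding electrodes, got {len(keys)}")
    x = np.array([latencies_ms[k] for k in keys]) * 1e-3   # s
    y = np.array([distances_mm[k] for k in keys])          # mm
    res = stats.linregress(x, y)
    dof = len(keys) - 2
    tq = stats.t.ppf(0.975, dof)
    half = tq * res.stderr if np.isfinite(res.stderr) else 0.0
    return VelocityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_low=float(res.slope - half),
        ci_high=float(res.slope + half),
        stderr=float(res.stderr),
        n=len(keys),
        direction=direction,
        r_value=float(res.rvalue),
    )


def compare_velocities(latencies_ms: Dict[int, float],
                       distances_mm: Dict[int, float],
                       subset_a: Iterable[int], subset_b: Iterable[int]
                       ) -> Tuple[float, float]:
    """Two-tailed unpaired t-test on per-electrode implied velocities.

    The implied velocity of one electrode is distance / latency (mm/s);
    the two direction groups are compared as independent samples.
    """
    def implied(subset):
        vals = []
        for k in subset:
            lat = latencies_ms.get(k, float("nan"))
            if np.isfinite(lat) and lat > 0:
                vals.append(distances_mm[k] / (lat * 1e-3))
        return np.array(vals)

    va, vb = implied(subset_a), implied(subset_b)
    if va.size < 2 or vb.size < 2:
        raise ValueError("need >= 2 implied velocities per group")
    if va.std() == 0 and vb.std() == 0 and va.mean() == vb.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(va, vb, equal_var=True)
    return float(t), float(p)


def velocity_table(latency_map: LatencyMap, layout: ArrayLayout,
                   stim_electrode: int,
                   tolerance: Optional[float] = None):
    """Tidy per-electrode table (electrode, distance, latency, direction)."""
    import pandas as pd

    distances = electrode_distances(layout, stim_electrode)
    directions = classify_direction(layout, stim_electrode, tolerance)
    rows = [
        {
            "electrode": eid,
            "distance_mm": distances[eid],
            "latency_ms": latency_map.mean_latency.get(eid, float("nan")),
            "direction": directions[eid],
            "n_responding": latency_map.n_responding.get(eid, 0),
        }
        for eid in layout.electrode_ids
    ]
    return pd.DataFrame(rows)
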