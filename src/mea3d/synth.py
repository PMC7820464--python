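"""Ground-truth generator for developing, compartmentalized 3D networks.

Emulates the statistical structure of the recordings the analysis pipeline
consumes: two somatic neuron populations flanking a cell-free neurite
corridor, distance-dependent synaptogenesis maturing over days in vitro
(DIV), spontaneous Poisson firing with propagating network bursts,
optogenetic activation cascades with per-synapse delays, pharmacological
silencing (CNQX/AP5, TTX), and electrode pickup with raw-trace synthesis.

Every operation is deterministic under ``SynthConfig.seed``; independent
random substreams are derived per stage so that, e.g., adding stimulation
does not perturb the spontaneous background.
"""

from __future__ import annotations

import heapq
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import RawTraceSet, SpikeTrainSet, StimProtocol
from .geometry import ArrayLayout, Region, TissueSpec

__all__ = [
    "SynthConfig",
    "GroundTruthNetwork",
    "maturation",
    "generate_network",
    "simulate_spontaneous",
    "simulate_stimulation",
    "apply_blocker",
    "map_to_electrodes",
    "synthesize_raw",
    "velocity_scenario",
    "sphere_predicate",
]


@dataclass
class SynthConfig:
    """Generative parameters; defaults are the package's study conditions.

    Rates and connectivity mature with DIV through a logistic factor
    centred at DIV 10 (``maturation``), reflecting the surge of synapse
    formation after day 10 in these cultures.
    """

    neurons_per_somatic_region: int = 1000
    chr2_fraction: float = 0.8
    div: float = 14.0
    # single-group preparation: neurons uniform over the whole tissue (the
    # model used for the spontaneous maturation analyses); the default
    # two-group model confines somata to the two somatic compartments
    single_group: bool = False

    # connectivity: P(i->j) = p0 * exp(-d/λ) * maturation(div)
    connection_p0: float = 0.3
    connection_lambda: float = 150.0        # μm
    axonal_velocity: float = 500.0          # mm/s
    synaptic_delay_range: Tuple[float, float] = (1.0, 4.0)  # ms per synapse
    transmission_probability: float = 0.3
    excitatory_fraction: float = 1.0

    # firing-rate schedules (Hz), linear in the maturation factor; the
    # mature balance puts most spikes inside network bursts, as in
    # synchronized mature cultures
    base_rate_min: float = 0.02
    base_rate_max: float = 0.5
    burst_rate_min: float = 0.02            # network burst events per second
    burst_rate_max: float = 0.35
    burst_spread_min: float = 200.0         # μm, burst recruitment radius
    burst_spread_max: float = 2500.0
    burst_participation: float = 0.8
    burst_spike_jitter: float = 1.5e-3      # s, per-neuron jitter on burst spikes
    burst_spike_prob: float = 0.9           # P(participant emits each burst spike)

    # fraction of neurons that fire at all, growing with maturation
    firing_fraction_min: float = 0.15

    maturation_midpoint: float = 10.0       # DIV
    maturation_steepness: float = 1.0       # DIV

    refractory: float = 2.0                 # ms
    activation_jitter: Tuple[float, float] = (1.0, 3.0)  # ms, ChR2 latency-to-spike
    # illuminated ChR2 neurons keep firing through the pulse (sustained
    # photocurrent); the first spike still follows the activation jitter
    sustained_drive_rate: float = 8.0       # Hz during the light pulse
    max_spikes_per_pulse: int = 12          # synaptic-depression cap per neuron

    # pickup radius close to half the 85 μm electrode pitch: adjacent sites
    # share ~1 % of units, so synchrony reflects the network, not pickup
    detection_radius: float = 50.0          # μm
    # neurite-region electrodes sense axons of cross-region projections
    axonal_pickup: bool = True
    axonal_amplitude_scale: float = 0.5
    amplitude_range: Tuple[float, float] = (150.0, 300.0)  # μV at the soma
    amplitude_halfwidth: float = 100.0      # μm, pickup decay scale
    noise_sd: float = 16.7                  # μV (3x noise ≈ 50 μV)
    sample_rate: float = 20_000.0           # S/s

    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.synaptic_delay_range
        if lo < 0 or lo > hi:
            raise ValueError("invalid synaptic delay range")
        for name in ("base_rate_min", "base_rate_max", "burst_rate_min",
                     "burst_rate_max", "transmission_probability"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.chr2_fraction <= 1:
            raise ValueError("chr2_fraction must be in [0, 1]")
        if not 0 <= self.connection_p0 <= 1:
            raise ValueError("connection_p0 must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent substream derived from the master seed."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)

    def base_rate(self, div: Optional[float] = None) -> float:
        m = maturation(self.div if div is None else div,
                       self.maturation_midpoint, self.maturation_steepness)
        return self.base_rate_min + (self.base_rate_max - self.base_rate_min) * m

    def burst_rate(self, div: Optional[float] = None) -> float:
        m = maturation(self.div if div is None else div,
                       self.maturation_midpoint, self.maturation_steepness)
        return self.burst_rate_min + (self.burst_rate_max - self.burst_rate_min) * m

    def burst_spread(self, div: Optional[float] = None) -> float:
        m = maturation(self.div if div is None else div,
                       self.maturation_midpoint, self.maturation_steepness)
        return self.burst_spread_min + (self.burst_spread_max - self.burst_spread_min) * m

    def firing_fraction(self, div: Optional[float] = None) -> float:
        m = maturation(self.div if div is None else div,
                       self.maturation_midpoint, self.maturation_steepness)
        return self.firing_fraction_min + (1.0 - self.firing_fraction_min) * m


def maturation(div: float, midpoint: float = 10.0, steepness: float = 1.0) -> float:
    """Logistic DIV maturation factor in (0, 1), centred at ``midpoint``."""
    return float(1.0 / (1.0 + np.exp(-(div - midpoint) / steepness)))


@dataclass
class GroundTruthNetwork:
    """Synthetic neurons and their directed synapse graph.

    ``positions`` is (n, 3) in μm; ``synapses`` columns are pre- and
    post-synaptic neuron indices; ``delays`` the per-edge total conduction +
    synaptic delay in ms.  ``transmission_scale`` is 1 for intact edges and
    0 for pharmacologically blocked ones; ``silenced`` marks a TTX state in
    which no neuron spikes at all.
    """

    positions: np.ndarray                 # (n, 3) μm
    regions: np.ndarray                   # (n,) object array of Region
    chr2: np.ndarray                      # (n,) bool
    synapses: np.ndarray                  # (m, 2) int, columns (pre, post)
    delays: np.ndarray                    # (m,) ms, > 0
    excitatory: np.ndarray                # (m,) bool
    transmission_scale: np.ndarray = None  # (m,) float in [0, 1]
    silenced: bool = False
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.synapses = np.asarray(self.synapses, dtype=int).reshape(-1, 2)
        self.delays = np.asarray(self.delays, dtype=float)
        self.excitatory = np.asarray(self.excitatory, dtype=bool)
        if self.transmission_scale is None:
            self.transmission_scale = np.ones(len(self.synapses))
        if self.synapses.size:
            if self.synapses.min() < 0 or self.synapses.max() >= self.n_neurons:
                raise ValueError("synapse endpoints must be valid neuron indices")
            if np.any(self.delays <= 0):
                raise ValueError("synaptic delays must be positive")

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)

    def out_adjacency(self) -> Tuple[np.ndarray, np.ndarray]:
        """CSR-style (indptr, order) over synapses sorted by presynaptic id."""
        order = np.argsort(self.synapses[:, 0], kind="stable")
        indptr = np.searchsorted(self.synapses[order, 0], np.arange(self.n_neurons + 1))
        return indptr, order

    def to_json_dict(self) -> Dict:
        return {
            "positions_um": self.positions.tolist(),
            "regions": [r.value for r in self.regions],
            "chr2": self.chr2.astype(bool).tolist(),
            "synapses": self.synapses.tolist(),
            "delays_ms": self.delays.tolist(),
            "excitatory": self.excitatory.astype(bool).tolist(),
            "transmission_scale": self.transmission_scale.tolist(),
            "silenced": self.silenced,
        }

    @classmethod
    def from_json_dict(cls, d: Dict) -> "GroundTruthNetwork":
        return cls(
            positions=np.array(d["positions_um"], dtype=float),
            regions=np.array([Region(r) for r in d["regions"]], dtype=object),
            chr2=np.array(d["chr2"], dtype=bool),
            synapses=np.array(d["synapses"], dtype=int).reshape(-1, 2),
            delays=np.array(d["delays_ms"], dtype=float),
            excitatory=np.array(d["excitatory"], dtype=bool),
            transmission_scale=np.array(d["transmission_scale"], dtype=float),
            silenced=bool(d.get("silenced", False)),
        )


def generate_network(config: SynthConfig,
                     tissue: Optional[TissueSpec] = None) -> GroundTruthNetwork:
    """Place neurons in the two somatic boxes and draw the synapse graph.

    Connection probability between neurons at distance d is
    ``p0 * exp(-d/λ) * maturation(div)``; each synapse's delay is the
    straight-line conduction time ``d / axonal_velocity`` plus one draw from
    ``synaptic_delay_range``.  Inter-region axons route straight through the
    neurite corridor.
    """
    tissue = tissue or TissueSpec()
    rng = config.rng("network")
    n_side = config.neurons_per_somatic_region
    lx, ly, lz = tissue.dimensions
    b1, b2 = tissue.region_boundaries

    if config.single_group:
        positions = rng.uniform([0, 0, 0], [lx, ly, lz], size=(2 * n_side, 3))
        regions = np.array([tissue.region_of(p[0]) for p in positions],
                           dtype=object)
    else:
        pos1 = rng.uniform([0, 0, 0], [b1, ly, lz], size=(n_side, 3))
        pos2 = rng.uniform([b2, 0, 0], [lx, ly, lz], size=(n_side, 3))
        positions = np.vstack([pos1, pos2])
        regions = np.array(
            [Region.SOMATIC1] * n_side + [Region.SOMATIC2] * n_side,
            dtype=object)
    chr2 = rng.random(2 * n_side) < config.chr2_fraction

    n = 2 * n_side
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    m = maturation(config.div, config.maturation_midpoint, config.maturation_steepness)
    prob = config.connection_p0 * np.exp(-dist / config.connection_lambda) * m
    np.fill_diagonal(prob, 0.0)
    connected = rng.random((n, n)) < prob
    pre, post = np.nonzero(connected)

    lo, hi = config.synaptic_delay_range
    syn_delay = rng.uniform(lo, hi, size=pre.size)
    conduction = dist[pre, post] / config.axonal_velocity  # μm / (mm/s) = ms
    delays = conduction + syn_delay
    excitatory = rng.random(pre.size) < config.excitatory_fraction

    return GroundTruthNetwork(
        positions=positions,
        regions=regions,
        chr2=chr2,
        synapses=np.column_stack([pre, post]),
        delays=delays,
        excitatory=excitatory,
        meta={"div": config.div, "seed": config.seed},
    )


def _enforce_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Keep the earliest spike of any run closer than the refractory period."""
    if times.size < 2:
        return times
    times = np.sort(times)
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.array(kept)


def simulate_spontaneous(network: GroundTruthNetwork, config: SynthConfig,
                         duration: float,
                         rng_stream: str = "spontaneous") -> SpikeTrainSet:
    """Per-neuron spontaneous activity: Poisson firing plus network bursts.

    Burst events initiate at a random neuron at Poisson times
    (``burst_rate(div)`` events/s); neurons within the DIV-dependent
    recruitment radius join with probability ``burst_participation`` and
    emit a jittered copy of a shared 3-10-spike skeleton (intra-burst ISIs
    well below 100 ms), modelling the propagating synchronous bursts of
    maturing cultures.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = config.rng(rng_stream)
    n = network.n_neurons
    refractory_s = config.refractory * 1e-3
    spikes: List[List[float]] = [[] for _ in range(n)]

    if not network.silenced:
        # immature neurons are silent; the firing pool grows with DIV
        firing = rng.random(n) < config.firing_fraction()
        base = config.base_rate()
        if base > 0:
            counts = rng.poisson(base * duration, size=n) * firing
            for i in range(n):
                if counts[i]:
                    spikes[i].extend(rng.uniform(0, duration, size=counts[i]))

        # network bursts propagate through excitatory synapses: blocking
        # them (CNQX/AP5) abolishes the bursts while tonic firing persists
        burst_rate = (0.0 if network.meta.get("blocker") == "CNQX_AP5"
                      else config.burst_rate())
        n_bursts = rng.poisson(burst_rate * duration) if burst_rate > 0 else 0
        spread = config.burst_spread()
        for _ in range(n_bursts):
            t0 = rng.uniform(0, duration)
            origin = network.positions[rng.integers(n)]
            n_sp = rng.integers(3, 11)
            isis = rng.uniform(0.01, 0.08, size=n_sp - 1)
            skeleton = t0 + np.concatenate([[0.0], np.cumsum(isis)])
            d = np.linalg.norm(network.positions - origin, axis=1)
            members = np.nonzero(
                (d <= spread) & firing & (rng.random(n) < config.burst_participation)
            )[0]
            for i in members:
                emit = rng.random(n_sp) < config.burst_spike_prob
                if not emit.any():
                    continue
                jitter = rng.normal(0.0, config.burst_spike_jitter, size=int(emit.sum()))
                spikes[i].extend(skeleton[emit] + jitter)

    trains = {}
    for i in range(n):
        t = np.array(spikes[i], dtype=float)
        t = t[(t >= 0) & (t <= duration)]
        trains[i] = _enforce_refractory(t, refractory_s)
    return SpikeTrainSet(trains=trains, duration=duration,
                         meta={"div": config.div, "scenario": "spontaneous",
                               "seed": config.seed})


def simulate_stimulation(network: GroundTruthNetwork, config: SynthConfig,
                         protocol: StimProtocol,
                         illuminated_region: Callable[[np.ndarray], np.ndarray],
                         duration: Optional[float] = None,
                         background: bool = True) -> SpikeTrainSet:
    """Optogenetic activation cascades superimposed on spontaneous firing.

    At each LED onset, ChR2-expressing neurons inside ``illuminated_region``
    fire after a short activation jitter; each spike then triggers each
    outgoing synapse with ``transmission_probability`` after the edge's
    total delay.  The refractory period and a per-pulse spike cap (synaptic
    depression) bound reverberation.  No evoked spike precedes its trigger.
    """
    duration = float(duration if duration is not None else protocol.end)
    if protocol.onsets[-1] + protocol.pulse_width > duration:
        raise ValueError("stimulation protocol extends past the recording")
    rng = config.rng("stimulation")
    refractory_s = config.refractory * 1e-3

    base = (
        simulate_spontaneous(network, config, duration)
        if background
        else SpikeTrainSet({i: np.array([]) for i in range(network.n_neurons)}, duration)
    )
    if network.silenced:
        return SpikeTrainSet(
            {i: np.array([]) for i in range(network.n_neurons)}, duration,
            meta={"div": config.div, "scenario": "stimulation+TTX",
                  "seed": config.seed})

    lit = np.asarray(illuminated_region(network.positions), dtype=bool)
    drivers = np.nonzero(lit & network.chr2)[0]
    indptr, order = network.out_adjacency()
    syn_post = network.synapses[order, 1]
    syn_delay_s = network.delays[order] * 1e-3
    syn_p = config.transmission_probability * network.transmission_scale[order]

    lo, hi = config.activation_jitter
    evoked: List[List[float]] = [[] for _ in range(network.n_neurons)]
    last_spike = np.full(network.n_neurons, -np.inf)
    onsets = protocol.onsets

    for pulse_idx, onset in enumerate(onsets):
        heap: List[Tuple[float, int]] = []
        pulse_count = np.zeros(network.n_neurons, dtype=int)
        for i in drivers:
            first = onset + rng.uniform(lo, hi) * 1e-3
            heapq.heappush(heap, (first, int(i)))
            if config.sustained_drive_rate > 0:
                window = onset + protocol.pulse_width - first
                n_extra = rng.poisson(config.sustained_drive_rate * max(window, 0.0))
                for t_extra in rng.uniform(first, onset + protocol.pulse_width,
                                           size=n_extra):
                    heapq.heappush(heap, (float(t_extra), int(i)))
        while heap:
            t, i = heapq.heappop(heap)
            if t > duration:
                continue
            if t - last_spike[i] < refractory_s:
                continue
            if pulse_count[i] >= config.max_spikes_per_pulse:
                continue
            last_spike[i] = t
            pulse_count[i] += 1
            evoked[i].append(t)
            s0, s1 = indptr[i], indptr[i + 1]
            if s0 == s1:
                continue
            fire = rng.random(s1 - s0) < syn_p[s0:s1]
            for k in np.nonzero(fire)[0]:
                heapq.heappush(heap, (t + syn_delay_s[s0 + k], int(syn_post[s0 + k])))

    trains = {}
    for i in range(network.n_neurons):
        merged = np.concatenate([base.trains[i], np.array(evoked[i], dtype=float)])
        merged = merged[(merged >= 0) & (merged <= duration)]
        trains[i] = _enforce_refractory(merged, refractory_s)
    return SpikeTrainSet(trains=trains, duration=duration,
                         meta={"div": config.div, "scenario": "stimulation",
                               "seed": config.seed})


def apply_blocker(network: GroundTruthNetwork, blocker: str) -> GroundTruthNetwork:
    """Return a pharmacologically modified copy of the network.

    ``CNQX_AP5`` zeroes transmission at excitatory synapses (spontaneous
    intrinsic firing is unchanged); ``TTX`` silences all spiking.  The input
    network is untouched, so a wash-out is simply the original object.
    """
    if blocker == "CNQX_AP5":
        scale = network.transmission_scale.copy()
        scale[network.excitatory] = 0.0
        return replace(network, transmission_scale=scale,
                       meta={**network.meta, "blocker": "CNQX_AP5"})
    if blocker == "TTX":
        return replace(network, silenced=True,
                       meta={**network.meta, "blocker": "TTX"})
    raise ValueError(f"unknown blocker {blocker!r}")


def map_to_electrodes(neuron_trains: SpikeTrainSet, network: GroundTruthNetwork,
                      layout: ArrayLayout, config: SynthConfig) -> SpikeTrainSet:
    """Project neuron spike trains onto the electrodes that sense them.

    A neuron contributes its spikes to every electrode within
    ``detection_radius``; per-electrode trains are merged, sorted, and
    tagged with amplitudes that decay with soma-electrode distance as
    ``amp / (1 + (d / halfwidth)^2)``.  With ``axonal_pickup`` enabled,
    electrodes in the neurite region additionally sense the axons of
    cross-region projections passing within the pickup radius: they record
    the presynaptic neuron's spikes delayed by the conduction time to the
    closest axonal point, at reduced amplitude.  Neurite-region signals
    therefore appear only once inter-region connectivity exists, as in the
    maturing preparation.
    """
    epos = layout.positions()
    eids = layout.electrode_ids
    amp_rng = config.rng("amplitudes")
    soma_amp = amp_rng.uniform(*config.amplitude_range, size=network.n_neurons)

    axonal = _axonal_pickup_map(network, layout, config) if config.axonal_pickup else {}

    d = np.linalg.norm(network.positions[:, None, :] - epos[None, :, :], axis=-1)
    trains: Dict[int, np.ndarray] = {}
    amps: Dict[int, np.ndarray] = {}
    for col, eid in enumerate(eids):
        near = np.nonzero(d[:, col] <= config.detection_radius)[0]
        times = [neuron_trains.trains[i] for i in near if i in neuron_trains.trains]
        gains = [
            np.full(neuron_trains.trains[i].size,
                    soma_amp[i] / (1.0 + (d[i, col] / config.amplitude_halfwidth) ** 2))
            for i in near if i in neuron_trains.trains
        ]
        for i, delay_s in axonal.get(eid, []):
            if i in neuron_trains.trains:
                times.append(neuron_trains.trains[i] + delay_s)
                gains.append(np.full(
                    neuron_trains.trains[i].size,
                    config.axonal_amplitude_scale * soma_amp[i]))
        if times:
            t = np.concatenate(times)
            a = np.concatenate(gains)
            ok = (t >= 0) & (t <= neuron_trains.duration)
            t, a = t[ok], a[ok]
            idx = np.argsort(t, kind="stable")
            t, a = t[idx], a[idx]
            # coincident pickups within 0.5 ms merge into one multi-unit event
            if t.size > 1:
                keep = np.concatenate([[True], np.diff(t) > 5e-4])
                t, a = t[keep], a[keep]
        else:
            t, a = np.array([]), np.array([])
        trains[eid] = t
        amps[eid] = a
    return SpikeTrainSet(trains=trains, duration=neuron_trains.duration,
                         meta=dict(neuron_trains.meta), amplitudes=amps)


def _axonal_pickup_map(network: GroundTruthNetwork, layout: ArrayLayout,
                       config: SynthConfig) -> Dict[int, List[Tuple[int, float]]]:
    """Neurite-region electrode -> [(presynaptic neuron, conduction delay s)].

    An electrode senses the axon of a cross-region synapse when the
    straight soma-to-soma segment passes within ``detection_radius``; the
    delay is the conduction time from the presynaptic soma to the closest
    axonal point.  One entry per presynaptic neuron per electrode (the
    closest passing axon wins).
    """
    out: Dict[int, List[Tuple[int, float]]] = {}
    if network.n_synapses == 0:
        return out
    regions = network.regions
    pre, post = network.synapses[:, 0], network.synapses[:, 1]
    cross = np.nonzero(
        np.array([regions[i] != regions[j] for i, j in zip(pre, post)])
    )[0]
    if cross.size == 0:
        return out
    a = network.positions[pre[cross]]
    b = network.positions[post[cross]]
    ab = b - a
    ab_len2 = (ab**2).sum(axis=1)
    for e in layout.electrodes:
        if e.region != Region.NEURITE:
            continue
        p = np.array(e.position)
        t = np.clip(((p - a) * ab).sum(axis=1) / np.maximum(ab_len2, 1e-12), 0, 1)
        closest = a + t[:, None] * ab
        dist = np.linalg.norm(closest - p, axis=1)
        near = np.nonzero(dist <= config.detection_radius)[0]
        if near.size == 0:
            continue
        best: Dict[int, Tuple[float, float]] = {}
        for k in near:
            neuron = int(pre[cross[k]])
            along_um = float(t[k] * np.sqrt(ab_len2[k]))
            delay_s = along_um / config.axonal_velocity * 1e-3  # μm/(mm/s) = ms
            if neuron not in best or dist[k] < best[neuron][0]:
                best[neuron] = (float(dist[k]), delay_s)
        out[e.id] = [(n, dl) for n, (_, dl) in sorted(best.items())]
    return out


def _spike_template(sample_rate: float) -> np.ndarray:
    """Biphasic extracellular template, unit negative peak, ~1 ms support."""
    t = np.arange(-0.3e-3, 0.7e-3, 1.0 / sample_rate)
    wave = -np.exp(-(t / 0.12e-3) ** 2) + 0.3 * np.exp(-((t - 0.3e-3) / 0.25e-3) ** 2)
    return wave / np.abs(wave).max()


def synthesize_raw(electrode_trains: SpikeTrainSet,
                   config: SynthConfig) -> RawTraceSet:
    """Render electrode trains as sampled voltage traces with Gaussian noise.

    Each spike is a biphasic ~1 ms template scaled to its amplitude tag
    (default soma amplitudes 150-300 μV) added onto white noise of sd
    ``noise_sd`` (default 16.7 μV, so the 3x detection threshold sits near
    50 μV).  Overlapping templates sum.  Deterministic under the seed.
    """
    rng = config.rng("rawnoise")
    fs = config.sample_rate
    n_samples = int(round(electrode_trains.duration * fs))
    template = _spike_template(fs)
    pre = int(round(0.3e-3 * fs))
    traces: Dict[int, np.ndarray] = {}
    for eid in electrode_trains.channel_ids:
        trace = rng.normal(0.0, config.noise_sd, size=n_samples) if config.noise_sd > 0 \
            else np.zeros(n_samples)
        t = electrode_trains.trains[eid]
        if electrode_trains.amplitudes is not None and eid in electrode_trains.amplitudes \
                and electrode_trains.amplitudes[eid].size == t.size:
            amp = electrode_trains.amplitudes[eid]
        else:
            amp = rng.uniform(*config.amplitude_range, size=t.size)
        centers = np.round(t * fs).astype(int)
        for c, a in zip(centers, amp):
            start = c - pre
            i0, i1 = max(start, 0), min(start + template.size, n_samples)
            if i1 <= i0:
                continue
            trace[i0:i1] += a * template[i0 - start:i1 - start]
        traces[eid] = trace.astype(np.float32)
    return RawTraceSet(traces=traces, sample_rate=fs,
                       meta=dict(electrode_trains.meta))


def sphere_predicate(center: Sequence[float], radius: float):
    """Position predicate: within ``radius`` μm of ``center`` (tissue frame)."""
    c = np.asarray(center, dtype=float)

    def predicate(positions: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        return np.linalg.norm(p - c, axis=-1) <= radius

    return predicate


# -- velocity-recovery scenario ---------------------------------------------

def velocity_scenario(layout: ArrayLayout, config: Optional[SynthConfig] = None,
                      v_longitudinal: float = 500.0, v_transverse: float = 250.0,
                      base_synaptic_delay: float = 1.0,
                      latency_dispersion: float = 0.02,
                      soma_offset: float = 25.0,
                      stim_electrode: int = 1,
                      seed: int = 0) -> Tuple[GroundTruthNetwork, SynthConfig, Dict]:
    """Two-group network with injected direction-dependent velocities.

    Builds synaptic chains from a ChR2 neuron at the stimulation electrode
    to one target neuron near every electrode of the longitudinal row and
    the transverse column (the direction-pure analysis set).  Each target
    soma sits a random offset (up to ``soma_offset`` μm, inside the pickup
    radius) from its electrode — the dominant scatter of the distance-
    versus-latency regression, landing in the distance axis as in the real
    preparation.  A chain's total delay is ``base_synaptic_delay +
    soma distance / v(direction)`` plus a small per-electrode dispersion,
    decomposed into per-hop synaptic delays within the 1-4 ms
    single-synapse band.  Relay neurons sit at z = 140 μm, clear of every
    electrode's pickup radius, so the first evoked spike at each electrode
    realizes exactly the injected travel time.

    Returns the network, a scenario config (quiet background, 30 μm pickup
    radius, unit transmission), and an info dict with the per-electrode
    ground-truth delays and direction labels.
    """
    base = config or SynthConfig()
    scen = replace(
        base,
        seed=seed,
        base_rate_min=0.0, base_rate_max=0.0,
        burst_rate_min=0.0, burst_rate_max=0.0,
        transmission_probability=1.0,
        detection_radius=30.0,
        chr2_fraction=1.0,
        axonal_pickup=False,  # chain relays are not straight-line axons
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    delay_lo, delay_hi = scen.synaptic_delay_range

    stim = np.array(layout.electrode(stim_electrode).position)
    positions = [stim]
    chr2 = [True]
    synapses: List[Tuple[int, int]] = []
    delays: List[float] = []
    target_of: Dict[int, int] = {}
    truth: Dict[int, Dict] = {}

    for eid in layout.electrode_ids:
        if eid == stim_electrode:
            continue
        epos = np.array(layout.electrode(eid).position)
        edelta = epos - stim
        tol = min(layout.row_pitch, layout.column_pitch) / 2.0
        if abs(edelta[1]) <= tol and abs(edelta[0]) > tol:
            direction, v = "longitudinal", v_longitudinal
        elif abs(edelta[0]) <= tol and abs(edelta[1]) > tol:
            direction, v = "transverse", v_transverse
        else:
            continue  # off-axis electrodes stay silent in this preparation

        # soma displaced uniformly within a ball around the electrode
        u = rng.normal(size=3)
        u *= soma_offset * rng.random() ** (1 / 3) / np.linalg.norm(u)
        soma = epos + u
        delta = soma - stim
        dist = float(np.linalg.norm(delta))
        total = base_synaptic_delay + dist / v + rng.normal(0.0, latency_dispersion)
        total = max(total, delay_lo + 0.05)
        n_hops = max(1, int(np.ceil(total / delay_hi)))
        hop = total / n_hops
        if hop < delay_lo:  # single short monosynaptic contact
            n_hops, hop = 1, total

        prev = 0
        for h in range(1, n_hops + 1):
            p = stim + (h / n_hops) * delta
            if h < n_hops:
                p = np.array([p[0], p[1], 140.0])  # relay clear of all electrodes
            idx = len(positions)
            positions.append(p)
            chr2.append(False)
            synapses.append((prev, idx))
            delays.append(hop)
            prev = idx
        target_of[eid] = prev
        truth[eid] = {
            "direction": direction,
            "distance_mm": dist / 1000.0,
            "delay_ms": float(total),
        }

    positions = np.array(positions)
    tissue = TissueSpec()
    regions = np.array([tissue.region_of(p[0]) for p in positions], dtype=object)
    network = GroundTruthNetwork(
        positions=positions,
        regions=regions,
        chr2=np.array(chr2, dtype=bool),
        synapses=np.array(synapses, dtype=int).reshape(-1, 2),
        delays=np.array(delays, dtype=float),
        excitatory=np.ones(len(synapses), dtype=bool),
        meta={"scenario": "velocity", "v_longitudinal": v_longitudinal,
              "v_transverse": v_transverse, "seed": seed},
    )
    info = {
        "stim_electrode": stim_electrode,
        "target_of": target_of,
        "truth": truth,
        "v_longitudinal": v_longitudinal,
        "v_transverse": v_transverse,
    }
    return network, scen, info
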