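"""Synthetic-data generator tests: determinism, causality, ground truth."""

import numpy as np
import pytest
from dataclasses import replace

from mea3d.core import StimProtocol
from mea3d.geometry import Region, TissueSpec
from mea3d.synth import (
    GroundTruthNetwork,
    SynthConfig,
    apply_blocker,
    generate_network,
    map_to_electrodes,
    maturation,
    simulate_spontaneous,
    simulate_stimulation,
    sphere_predicate,
    synthesize_raw,
    velocity_scenario,
)


def chain_network(delays_ms, chr2_first=True):
    """Hand-built linear chain A -> B -> C ... with given edge delays."""
    n = len(delays_ms) + 1
    positions = np.column_stack([
        np.linspace(100, 100 + 50 * (n - 1), n),
        np.full(n, 500.0),
        np.full(n, 150.0),
    ])
    return GroundTruthNetwork(
        positions=positions,
        regions=np.array([Region.SOMATIC1] * n, dtype=object),
        chr2=np.array([chr2_first] + [False] * (n - 1)),
        synapses=np.array([[i, i + 1] for i in range(n - 1)]),
        delays=np.array(delays_ms, dtype=float),
        excitatory=np.ones(n - 1, dtype=bool),
    )


class TestGenerateNetwork:
    def test_zero_connection_scale_gives_no_synapses(self, tissue):
        cfg = SynthConfig(neurons_per_somatic_region=50, connection_p0=0.0, seed=1)
        assert generate_network(cfg, tissue).n_synapses == 0

    def test_determinism_under_seed(self, tissue, small_config):
        a = generate_network(small_config, tissue)
        b = generate_network(small_config, tissue)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.synapses, b.synapses)
        assert np.array_equal(a.delays, b.delays)

    def test_saturated_config_connects_every_pair(self, tissue):
        # p0=1, huge λ, mature culture: expected edges ≈ N(N-1) x maturation
        cfg = SynthConfig(neurons_per_somatic_region=20, connection_p0=1.0,
                          connection_lambda=1e9, div=30.0, seed=2)
        net = generate_network(cfg, tissue)
        n = net.n_neurons
        m = maturation(30.0)
        expected = n * (n - 1) * m
        assert net.n_synapses == pytest.approx(expected, rel=0.05)
        # brute-force pair check: no self-loops, no duplicates
        pairs = {tuple(s) for s in net.synapses}
        assert len(pairs) == net.n_synapses
        assert all(i != j for i, j in pairs)

    def test_neurons_confined_to_somatic_boxes(self, tissue, small_config):
        net = generate_network(small_config, tissue)
        b1, b2 = tissue.region_boundaries
        x = net.positions[:, 0]
        assert np.all((x < b1) | (x > b2))
        assert {r for r in net.regions} == {Region.SOMATIC1, Region.SOMATIC2}

    def test_delays_exceed_conduction_time(self, tissue, small_config):
        net = generate_network(small_config, tissue)
        if net.n_synapses:
            d = np.linalg.norm(
                net.positions[net.synapses[:, 0]] - net.positions[net.synapses[:, 1]],
                axis=1)
            conduction = d / small_config.axonal_velocity
            lo, hi = small_config.synaptic_delay_range
            assert np.all(net.delays >= conduction + lo - 1e-9)
            assert np.all(net.delays <= conduction + hi + 1e-9)

    def test_connectivity_matures_with_div(self, tissue):
        counts = [
            generate_network(SynthConfig(neurons_per_somatic_region=150,
                                         div=d, seed=5), tissue).n_synapses
            for d in (6, 10, 14)
        ]
        assert counts[0] < counts[1] < counts[2]


class TestSpontaneous:
    def test_silent_config_gives_empty_trains(self, tissue):
        cfg = SynthConfig(neurons_per_somatic_region=30, base_rate_min=0,
                          base_rate_max=0, burst_rate_min=0, burst_rate_max=0,
                          seed=1)
        net = generate_network(cfg, tissue)
        trains = simulate_spontaneous(net, cfg, 10.0)
        assert trains.n_spikes() == 0

    def test_poisson_rate_within_three_sigma(self, tissue):
        # flat 2 Hz, no bursts, every neuron firing: 300 s -> 600 ± 3√600
        cfg = SynthConfig(neurons_per_somatic_region=60, base_rate_min=2.0,
                          base_rate_max=2.0, burst_rate_min=0, burst_rate_max=0,
                          firing_fraction_min=1.0, div=30, seed=4)
        net = generate_network(cfg, tissue)
        trains = simulate_spontaneous(net, cfg, 300.0)
        counts = np.array([trains.trains[i].size for i in range(net.n_neurons)])
        assert abs(counts.mean() - 600) < 3 * np.sqrt(600 / len(counts))

    def test_mature_networks_fire_more(self, tissue):
        rates = []
        for div in (6, 14):
            cfg = SynthConfig(neurons_per_somatic_region=150, div=div, seed=9)
            net = generate_network(cfg, tissue)
            trains = simulate_spontaneous(net, cfg, 120.0)
            rates.append(trains.n_spikes() / 120.0)
        assert rates[1] > rates[0]

    def test_refractory_enforced(self, tissue, small_config):
        net = generate_network(small_config, tissue)
        trains = simulate_spontaneous(net, small_config, 60.0)
        for t in trains.trains.values():
            if t.size > 1:
                assert np.diff(t).min() >= small_config.refractory * 1e-3 - 1e-12


class TestStimulationCascade:
    def test_three_neuron_chain_arrival_time(self):
        # A -> B -> C with 2 and 3 ms delays, no jitter: C fires 5 ms after A
        net = chain_network([2.0, 3.0])
        cfg = SynthConfig(transmission_probability=1.0, activation_jitter=(0, 0),
                          base_rate_min=0, base_rate_max=0, burst_rate_min=0,
                          burst_rate_max=0, sustained_drive_rate=0.0, seed=1)
        proto = StimProtocol(n_trials=1, start=1.0)
        trains = simulate_stimulation(net, cfg, proto,
                                      lambda p: np.ones(len(p), bool),
                                      duration=proto.end)
        assert trains.trains[0].size == 1
        a, c = trains.trains[0][0], trains.trains[2][0]
        assert c - a == pytest.approx(5e-3, abs=1e-9)
        # causality along the chain
        assert trains.trains[0][0] < trains.trains[1][0] < trains.trains[2][0]

    def test_no_chr2_no_evoked_modulation(self, tissue):
        cfg = SynthConfig(neurons_per_somatic_region=80, chr2_fraction=0.0, seed=6)
        net = generate_network(cfg, tissue)
        proto = StimProtocol(n_trials=2)
        spont = simulate_spontaneous(net, cfg, proto.end)
        stim = simulate_stimulation(net, cfg, proto,
                                    lambda p: np.ones(len(p), bool),
                                    duration=proto.end)
        # identical spontaneous substream: stimulation adds nothing
        assert stim.n_spikes() == spont.n_spikes()

    def test_mature_cascade_reaches_all_regions(self, layout, tissue):
        cfg = SynthConfig(div=14, seed=11)
        net = generate_network(cfg, tissue)
        proto = StimProtocol(n_trials=2)
        lit = sphere_predicate(layout.electrode(1).position, 220.0)
        trains = simulate_stimulation(net, cfg, proto, lit, duration=proto.end,
                                      background=False)
        fired = {net.regions[i] for i in trains.trains if trains.trains[i].size}
        assert fired == {Region.SOMATIC1, Region.SOMATIC2}
        # reachability oracle: every firing neuron is reachable from a driver
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(range(net.n_neurons))
        g.add_edges_from(map(tuple, net.synapses))
        drivers = {i for i in np.nonzero(net.chr2)[0]
                   if lit(net.positions[i][None, :])[0]}
        reach = set(drivers)
        for d in drivers:
            reach |= nx.descendants(g, d)
        assert {i for i in trains.trains if trains.trains[i].size} <= reach

    def test_no_evoked_spike_precedes_stimulus(self, tissue, small_config):
        net = generate_network(small_config, tissue)
        proto = StimProtocol(n_trials=2)
        lit = sphere_predicate((100, 500, 150), 400.0)
        trains = simulate_stimulation(net, small_config, proto, lit,
                                      duration=proto.end, background=False)
        for t in trains.trains.values():
            assert t.size == 0 or t.min() >= proto.onsets[0]


class TestBlockers:
    def test_ttx_silences_everything(self, tissue, small_config):
        net = generate_network(small_config, tissue)
        blocked = apply_blocker(net, "TTX")
        proto = StimProtocol(n_trials=2)
        assert simulate_spontaneous(blocked, small_config, 30.0).n_spikes() == 0
        assert simulate_stimulation(
            blocked, small_config, proto, lambda p: np.ones(len(p), bool),
            duration=proto.end).n_spikes() == 0

    def test_cnqx_restricts_cascade_to_illuminated_neurons(self, tissue):
        cfg = SynthConfig(neurons_per_somatic_region=100, div=14,
                          base_rate_min=0, base_rate_max=0, burst_rate_min=0,
                          burst_rate_max=0, chr2_fraction=1.0, seed=8)
        net = generate_network(cfg, tissue)
        blocked = apply_blocker(net, "CNQX_AP5")
        center = net.positions[0]
        lit = sphere_predicate(center, 200.0)
        proto = StimProtocol(n_trials=1)
        trains = simulate_stimulation(blocked, cfg, proto, lit,
                                      duration=proto.end, background=False)
        fired = {i for i in trains.trains if trains.trains[i].size}
        illuminated = set(np.nonzero(lit(net.positions))[0])
        assert fired and fired <= illuminated  # graph-reachability collapses

    def test_washout_restores_cascade(self, tissue, small_config):
        net = generate_network(small_config, tissue)
        proto = StimProtocol(n_trials=1)
        lit = lambda p: np.ones(len(p), bool)
        before = simulate_stimulation(net, small_config, proto, lit,
                                      duration=proto.end, background=False)
        _ = apply_blocker(net, "CNQX_AP5")  # original untouched
        after = simulate_stimulation(net, small_config, proto, lit,
                                     duration=proto.end, background=False)
        for i in before.trains:
            assert np.array_equal(before.trains[i], after.trains[i])

    def test_unknown_blocker_rejected(self, tissue, small_config):
        net = generate_network(small_config, tissue)
        with pytest.raises(ValueError):
            apply_blocker(net, "caffeine")


class TestElectrodeMapping:
    def test_zero_radius_detects_nothing(self, layout, tissue, small_config):
        cfg = replace(small_config, detection_radius=0.0, axonal_pickup=False)
        net = generate_network(cfg, tissue)
        trains = simulate_spontaneous(net, cfg, 30.0)
        etrains = map_to_electrodes(trains, net, layout, cfg)
        assert etrains.n_spikes() == 0

    def test_single_nearby_neuron_maps_identically(self, layout):
        e = layout.electrode(30)
        pos = np.array(e.position) + np.array([5.0, 5.0, 5.0])
        net = GroundTruthNetwork(
            positions=pos[None, :],
            regions=np.array([e.region], dtype=object),
            chr2=np.array([False]),
            synapses=np.empty((0, 2), int), delays=np.empty(0),
            excitatory=np.empty(0, bool))
        from mea3d.core import SpikeTrainSet
        t = np.array([0.5, 1.0, 2.5])
        cfg = SynthConfig(axonal_pickup=False)
        etrains = map_to_electrodes(SpikeTrainSet({0: t}, 10.0), net, layout, cfg)
        assert np.array_equal(etrains.trains[e.id], t)
        others = [k for k in etrains.trains if k != e.id]
        assert all(etrains.trains[k].size == 0 for k in others)

    def test_two_neurons_merge_sorted(self, layout):
        e = layout.electrode(30)
        base = np.array(e.position)
        net = GroundTruthNetwork(
            positions=np.vstack([base + 8, base - 8]),
            regions=np.array([e.region] * 2, dtype=object),
            chr2=np.zeros(2, bool),
            synapses=np.empty((0, 2), int), delays=np.empty(0),
            excitatory=np.empty(0, bool))
        from mea3d.core import SpikeTrainSet
        t0 = np.array([0.5, 2.0]); t1 = np.array([1.0, 3.0])
        cfg = SynthConfig(axonal_pickup=False)
        etrains = map_to_electrodes(SpikeTrainSet({0: t0, 1: t1}, 10.0), net,
                                    layout, cfg)
        merged = np.sort(np.concatenate([t0, t1]))  # brute-force merge oracle
        assert np.array_equal(etrains.trains[e.id], merged)

    def test_neurite_electrodes_need_cross_region_axons(self, layout, tissue):
        cfg = SynthConfig(neurons_per_somatic_region=150, div=14, seed=13)
        net = generate_network(cfg, tissue)
        trains = simulate_spontaneous(net, cfg, 60.0)
        with_ax = map_to_electrodes(trains, net, layout, cfg)
        without = map_to_electrodes(trains, net, layout,
                                    replace(cfg, axonal_pickup=False))
        neurite = [e.id for e in layout.electrodes if e.region is Region.NEURITE]
        assert sum(without.trains[e].size for e in neurite) == 0
        assert sum(with_ax.trains[e].size for e in neurite) > 0


class TestRawSynthesis:
    def test_pure_noise_sd(self):
        from mea3d.core import SpikeTrainSet
        cfg = SynthConfig(seed=2)
        raw = synthesize_raw(SpikeTrainSet({0: np.array([])}, 5.0), cfg)
        assert raw.traces[0].std() == pytest.approx(cfg.noise_sd, rel=0.05)
        assert raw.n_samples == int(5.0 * cfg.sample_rate)

    def test_noiseless_single_spike_is_template(self):
        from mea3d.core import SpikeTrainSet
        cfg = SynthConfig(noise_sd=0.0, seed=2)
        ts = SpikeTrainSet({0: np.array([0.5])}, 1.0,
                           amplitudes={0: np.array([200.0])})
        raw = synthesize_raw(ts, cfg)
        trace = raw.traces[0]
        assert trace.min() == pytest.approx(-200.0, rel=1e-3)
        peak = np.argmin(trace)
        assert abs(peak / cfg.sample_rate - 0.5) < 1e-3
        outside = np.concatenate([trace[:peak - 40], trace[peak + 40:]])
        assert np.abs(outside).max() < 1e-6

    def test_determinism(self):
        from mea3d.core import SpikeTrainSet
        cfg = SynthConfig(seed=5)
        ts = SpikeTrainSet({0: np.array([0.2, 0.7])}, 1.0)
        a = synthesize_raw(ts, cfg)
        b = synthesize_raw(ts, cfg)
        assert np.array_equal(a.traces[0], b.traces[0])


class TestVelocityScenario:
    def test_direction_pure_sets_hold_19_and_7_electrodes(self, layout):
        _, _, info = velocity_scenario(layout, seed=0)
        dirs = [v["direction"] for v in info["truth"].values()]
        assert dirs.count("longitudinal") == 19
        assert dirs.count("transverse") == 7

    def test_injected_delays_decompose_into_single_synapse_hops(self, layout):
        net, _, info = velocity_scenario(layout, seed=0)
        lo, hi = SynthConfig().synaptic_delay_range
        assert net.delays.max() <= hi + 1e-9
        # summed chain delays reproduce the injected totals
        import networkx as nx
        g = nx.DiGraph()
        for (pre, post), d in zip(net.synapses, net.delays):
            g.add_edge(int(pre), int(post), delay=float(d))
        for eid, target in info["target_of"].items():
            path_delay = nx.shortest_path_length(g, 0, target, weight="delay")
            assert path_delay == pytest.approx(info["truth"][eid]["delay_ms"])
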