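"""Readers, writers, configuration, and the pipeline runner.

Conventions: spike times stored in seconds as float64 (HDF5 dataset per
electrode, or CSV with columns ``electrode,time_s``), coordinates in μm,
units recorded as attributes/headers.  Every pipeline run writes a manifest
(version, seeds, parameter hash) so numeric outputs are reproducible
bit-for-bit from their configuration.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Dict, Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import RawTraceSet, SpikeTrainSet, StimProtocol
from .geometry import ArrayLayout, TissueSpec, build_standard_array
from .synth import GroundTruthNetwork, SynthConfig

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "write_raw_traces",
    "read_raw_traces",
    "write_network",
    "read_network",
    "write_graphml",
    "load_config",
    "run_pipeline",
]

PathLike = Union[str, os.PathLike]


class ParseError(ValueError):
    """Malformed input file; the message names the offending record."""


# -- spike trains ------------------------------------------------------------

def write_spike_trains(train_set: SpikeTrainSet, path: PathLike) -> None:
    """Write to HDF5 (``trains/<id>`` datasets) or CSV by file extension."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            fh.attrs["duration_s"] = train_set.duration
            fh.attrs["units"] = "s"
            for key, value in train_set.meta.items():
                fh.attrs[f"meta_{key}"] = value
            grp = fh.create_group("trains")
            for eid, t in train_set.trains.items():
                grp.create_dataset(str(eid), data=t, dtype="f8")
    elif path.suffix == ".csv":
        rows = [
            {"electrode": eid, "time_s": t}
            for eid in train_set.channel_ids
            for t in train_set.trains[eid]
        ]
        pd.DataFrame(rows, columns=["electrode", "time_s"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported spike-train format {path.suffix!r}")


def read_spike_trains(path: PathLike,
                      duration: Optional[float] = None) -> SpikeTrainSet:
    """Read HDF5 or CSV spike trains; times are sorted on load."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            dur = float(fh.attrs["duration_s"]) if duration is None else duration
            meta = {
                k[len("meta_"):]: _as_py(v)
                for k, v in fh.attrs.items() if k.startswith("meta_")
            }
            trains = {
                int(name): np.sort(np.asarray(ds[()], dtype=float))
                for name, ds in fh["trains"].items()
            }
        return SpikeTrainSet(trains=trains, duration=dur, meta=meta)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        for col in ("electrode", "time_s"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing column {col!r}")
        bad = pd.to_numeric(df["time_s"], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based
            raise ParseError(f"{path}: non-numeric time at line {line}")
        times = df["time_s"].astype(float)
        dur = duration if duration is not None else float(times.max()) + 1e-6
        trains = {
            int(eid): np.sort(grp.to_numpy())
            for eid, grp in times.groupby(df["electrode"])
        }
        return SpikeTrainSet(trains=trains, duration=dur)
    raise ValueError(f"unsupported spike-train format {path.suffix!r}")


def _as_py(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


# -- raw traces --------------------------------------------------------------

def write_raw_traces(raw: RawTraceSet, path: PathLike) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["sample_rate"] = raw.sample_rate
        fh.attrs["units"] = "uV"
        grp = fh.create_group("traces")
        for eid, trace in raw.traces.items():
            grp.create_dataset(str(eid), data=trace, dtype="f4")


def read_raw_traces(path: PathLike) -> RawTraceSet:
    with h5py.File(path, "r") as fh:
        rate = float(fh.attrs["sample_rate"])
        traces = {int(k): np.asarray(v[()], dtype=np.float32)
                  for k, v in fh["traces"].items()}
    return RawTraceSet(traces=traces, sample_rate=rate)


# -- ground truth and graphs -------------------------------------------------

def write_network(network: GroundTruthNetwork, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(network.to_json_dict(), fh)


def read_network(path: PathLike) -> GroundTruthNetwork:
    with open(path) as fh:
        return GroundTruthNetwork.from_json_dict(json.load(fh))


def write_graphml(graph, partition, path: PathLike) -> None:
    """Graph + community labels + normalized degree as GraphML."""
    import networkx as nx

    g = graph.copy()
    for node in g.nodes:
        g.nodes[node]["community"] = int(partition.labels[node])
        g.nodes[node]["normalized_degree"] = float(
            partition.normalized_degree.get(node, 0.0))
    nx.write_graphml(g, path)


# -- configuration and pipeline ---------------------------------------------

def load_config(path: PathLike) -> Dict:
    """Structured text (YAML/JSON) run configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def _param_hash(obj) -> str:
    def default(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    text = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: Optional[Dict] = None, out_dir: PathLike = "results",
                 seed: int = 0) -> Dict:
    """Simulate -> metrics -> synchrony/network -> stimulation -> velocity
    (-> optics), writing every stage artifact plus a manifest.

    ``config`` keys (all optional): ``div``, ``duration``, ``stages`` (list
    among {"spontaneous", "stimulation", "velocity", "optics"}), ``synth``
    (SynthConfig field overrides), ``n_packets``.  Deterministic under
    ``seed``: identical configs give byte-identical numeric outputs.
    """
    from . import activity, stimulus, synchrony, velocity as vel
    from .optics import MCParams, axial_profile, run_mc, threshold_contour
    from .synth import (map_to_electrodes, simulate_spontaneous,
                        simulate_stimulation, sphere_predicate,
                        velocity_scenario)

    config = dict(config or {})
    stages = config.get("stages", ["spontaneous", "stimulation", "velocity"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tissue = TissueSpec()
    layout = build_standard_array(tissue)
    layout.to_json(out / "layout.json")
    synth_kwargs = dict(config.get("synth", {}))
    synth_kwargs.setdefault("div", config.get("div", 14.0))
    cfg = SynthConfig(seed=seed, **synth_kwargs)
    duration = float(config.get("duration", 60.0))
    results: Dict = {"seed": seed}

    if "spontaneous" in stages:
        from .synth import generate_network

        network = generate_network(cfg, tissue)
        write_network(network, out / "ground_truth.json")
        neuron_trains = simulate_spontaneous(network, cfg, duration)
        etrains = map_to_electrodes(neuron_trains, network, layout, cfg)
        write_spike_trains(etrains, out / "spont_trains.h5")
        table = activity.metrics_table(etrains, label={"div": cfg.div})
        table.to_csv(out / "activity_metrics.csv", index=False)
        mat = synchrony.sync_matrix(etrains)
        pd.DataFrame(mat.scores, index=mat.electrode_ids,
                     columns=mat.electrode_ids).to_csv(out / "sync_matrix.csv")
        nparams = synchrony.NetworkParams(seed=seed)
        graph = synchrony.build_graph(
            mat, nparams,
            positions={e.id: e.position for e in layout.electrodes})
        part = synchrony.louvain_partition(graph, nparams)
        write_graphml(graph, part, out / "network.graphml")
        summary = synchrony.network_summaries(part, graph, nparams)
        results["spontaneous"] = {
            "n_active_electrodes": activity.active_electrodes(etrains),
            "n_networks": summary["n_networks"],
            "mean_network_size": summary["mean_network_size"],
            "modularity": part.modularity,
        }

    if "stimulation" in stages or "velocity" in stages:
        protocol = StimProtocol()
        pd.DataFrame({"onset_s": protocol.onsets,
                      "offset_s": protocol.offsets}).to_csv(
            out / "stim_events.csv", index=False)

    if "stimulation" in stages:
        from .synth import generate_network

        network = generate_network(cfg, tissue)
        stim_pos = layout.electrode(1).position
        lit = sphere_predicate(stim_pos, 220.0)
        protocol = StimProtocol()
        trains = simulate_stimulation(network, cfg, protocol, lit,
                                      duration=protocol.end + 1.0)
        etrains = map_to_electrodes(trains, network, layout, cfg)
        write_spike_trains(etrains, out / "stim_trains.h5")
        rates = stimulus.epoch_rates(etrains, protocol)
        rmap = stimulus.rate_increase_map(rates, layout)
        rmap.to_csv(out / "rate_increase_map.csv", index=False)
        results["stimulation"] = {
            "mean_delta_rate": float(rmap["delta_rate"].mean()),
            "n_no_signal": int(rmap["no_signal"].sum()),
        }

    if "velocity" in stages:
        network, scen, info = velocity_scenario(layout, cfg, seed=seed)
        protocol = StimProtocol()
        stim_pos = layout.electrode(info["stim_electrode"]).position
        trains = simulate_stimulation(
            network, scen, protocol, sphere_predicate(stim_pos, 50.0),
            duration=protocol.end + 1.0, background=False)
        etrains = map_to_electrodes(trains, network, layout, scen)
        lat = stimulus.estimate_latency(etrains, protocol)
        table = vel.velocity_table(lat, layout, info["stim_electrode"])
        table.to_csv(out / "latency_map.csv", index=False)
        distances = vel.electrode_distances(layout, info["stim_electrode"])
        directions = vel.classify_direction(layout, info["stim_electrode"])
        fits = {}
        for direction in ("all", "longitudinal", "transverse"):
            subset = [e for e in lat.defined()
                      if direction == "all" or directions[e] == direction]
            if len(subset) >= 3:
                fit = vel.fit_velocity(lat.mean_latency, distances, subset,
                                       direction)
                fits[direction] = {
                    "slope_mm_s": fit.slope, "ci": [fit.ci_low, fit.ci_high],
                    "n": fit.n,
                }
        with open(out / "velocity_fits.json", "w") as fh:
            json.dump(fits, fh, indent=1)
        results["velocity"] = fits

    if "optics" in stages:
        res = run_mc(params=MCParams(
            n_packets=int(config.get("n_packets", 200_000)), seed=seed))
        depths, profile = axial_profile(res)
        pd.DataFrame({"depth_um": depths, "irradiance_mw_mm2": profile}).to_csv(
            out / "axial_profile.csv", index=False)
        contour = threshold_contour(res)
        results["optics"] = contour
    else:
        results["optics"] = "skipped"

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "stages": stages,
        "param_hash": _param_hash({"config": config, "seed": seed}),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump({"manifest": manifest, "results": results}, fh, indent=1,
                  default=float)
    return results
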