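# mea3d

Analysis pipeline for neural-circuit dynamics recorded with a 3D
high-density multifunctional microelectrode array (MEA) in engineered 3D
neural tissue.

The device this package models is an 18-shank probe (3 × 6 grid, 500 /
360 μm pitches) carrying 63 recording microelectrodes (85 μm vertical
pitch), inserted in a 1.85 × 1 × 0.3 mm³ collagen construct that is either
uniform (single-group) or compartmentalized into two somatic regions
separated by a cell-free neurite corridor (two-group).  One multifunctional
shank additionally carries a thinned 50 μm-core optical fiber (LED-coupled,
473 nm) for local optogenetic stimulation and microfluidic channels for
drug delivery (CNQX/AP5, TTX).

`mea3d` implements the full analysis chain for such recordings, plus a
ground-truth synthetic-data generator so every stage is testable without
access to biological recordings:

- **geometry** — device/tissue geometry and the device-level quantities:
  shank volume occupancy, electrode density, LED/fiber optical budget,
  fiber-tip power density, photon rate, microchannel hydraulic flow.
- **synth** — generative model of a developing two-population 3D network:
  distance-dependent synaptogenesis maturing over days in vitro (DIV),
  Poisson firing with propagating network bursts, optogenetic activation
  cascades with per-synapse delays (1–4 ms), pharmacological silencing,
  electrode pickup and raw-trace synthesis (20 kS/s, ~16.7 μV noise).
- **detection** — zero-phase 300 Hz–6 kHz band-pass, robust MAD noise
  estimate, negative 3×-noise threshold crossings (~50 μV), SNR.
- **activity** — mean spike rate, active-electrode counts, ISI-threshold
  burst detection (0.1 s, ≥3 spikes) and burst statistics (rate, duration,
  spikes/burst, intra-burst ISI, IBI, % burst spikes).
- **synchrony** — SPIKE-synchronization (adaptive coincidence windows,
  scores 0–1), link filtering at 0.5, weighted graphs, seeded Louvain
  community detection, network counts / sizes / normalized degrees.
- **stimulus** — LED on/off epoch rates, two-tailed unpaired t-tests over
  stimulation trials, per-shank rate-increase maps, first-spike evoked
  latency with artifact blanking.
- **velocity** — distance-versus-latency regression; the slope is the
  synaptic transmission velocity (mm/s), overall and stratified into
  longitudinal (along the soma–neurite–soma axis) and transverse subsets.
- **optics** — voxelized Monte-Carlo photon transport in collagen
  (Henyey–Greenstein scattering, Russian roulette, collision-estimator
  fluence) predicting irradiance profiles and the ChR2 activation volume.
- **io / cli** — HDF5/CSV spike trains, JSON ground truth and fits,
  GraphML networks, YAML run configs, a manifest-writing pipeline runner,
  and a `mea3d` command-line interface.

## Worked example

Recover injected transmission velocities from a synthetic two-group
network.  The generator builds synaptic chains from a ChR2 neuron at the
stimulation electrode (electrode 1, shank 1) with a 2:1
longitudinal:transverse velocity ratio; the analysis measures first-spike
latencies after each light pulse (0.2 Hz, 2.5 s, six trials) and regresses
distance on latency:

```python
from mea3d.core import StimProtocol
from mea3d.geometry import build_standard_array, TissueSpec, \
    volume_occupancy, electrode_density
from mea3d.synth import velocity_scenario, simulate_stimulation, \
    map_to_electrodes, sphere_predicate
from mea3d import stimulus, velocity as vel

tissue = TissueSpec()
layout = build_standard_array(tissue)
print("occupancy %%: %.2f" % volume_occupancy(layout, tissue, 300.0))
print("sites/mm3: %d" % electrode_density(63, tissue.volume_mm3, "nearest"))

proto = StimProtocol()
net, scen, info = velocity_scenario(layout, seed=1)
trains = simulate_stimulation(
    net, scen, proto, sphere_predicate(layout.electrode(1).position, 50.0),
    duration=proto.end + 1.0, background=False)
etr = map_to_electrodes(trains, net, layout, scen)
lm = stimulus.estimate_latency(etr, proto)
dist = vel.electrode_distances(layout, 1)
dirs = vel.classify_direction(layout, 1)
responding = lm.defined()
for direction in ("longitudinal", "transverse"):
    fit = vel.fit_velocity(lm.mean_latency, dist,
                           [e for e in responding if dirs[e] == direction],
                           direction)
    print(f"{direction}: {fit.slope:.0f} mm/s "
          f"(95% CI {fit.ci_low:.0f}-{fit.ci_high:.0f}, n={fit.n})")
```

Output:

```
occupancy %: 2.63
sites/mm3: 114
longitudinal: 505 mm/s (95% CI 499-512, n=19)
transverse: 253 mm/s (95% CI 238-269, n=7)
```

The occupancy line says the inserted shanks displace 2.63 % of the tissue
(recording is close to non-invasive); 114 sites/mm³ is the volumetric
electrode coverage.  The fits recover the injected 500 / 250 mm/s
velocities within their confidence intervals from 19 longitudinal and 7
transverse responding electrodes, with evoked latencies in the
physiological 2–8 ms range.

The same pipeline runs from the shell:

```bash
mea3d velocity --seed 1 --out results/demo
mea3d all --seed 1 --out results/full   # adds spontaneous, stimulation, optics
```

## Documentation

`docs/methods.md` describes the generative model, the analysis methods and
their numerical choices, parameter defaults with units, and known
limitations.
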