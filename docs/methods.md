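# Methods

This note documents the models and procedures implemented in `mea3d`,
their assumptions, the parameters that matter (with units and defaults),
the numerical choices, and what the synthetic preparation does and does
not capture about real recordings.

## Device and tissue geometry

The standard array (`geometry.build_standard_array`) is a 3-row × 6-column
shank grid (row pitch 500 μm along y, column pitch 360 μm along x) with 63
electrodes distributed 3 or 4 per shank at 85 μm vertical pitch, the
lowest site 10 μm above the shank tip (the tip-clearance value is a
package choice; it keeps all sites within the 300 μm tissue depth).  The
multifunctional shank (145 μm wide; recording shanks 63 μm; all 40 μm
thick) sits at the corner of the first somatic region, and electrode 1 —
its lowest site — is the optical stimulation reference.  Shanks are
numbered region-major (1–6, 7–12, 13–18 for somatic-1, neurite,
somatic-2), electrodes 1–63 along shanks bottom-to-top.

The per-shank electrode counts are not uniquely determined by the total;
the assignment used here places 19 electrodes on the stimulation row and 7
on the stimulation column, matching the longitudinal / transverse
responding-electrode counts of the evoked-latency analysis.

Device-level quantities are closed-form: volume occupancy is
Σ(width × thickness × insertion depth) over shanks divided by the tissue
volume (2.63 % for the standard array at full 300 μm insertion);
electrode density is count/volume (114 sites/mm³ in the construct, 33.6 in
the 1.875 mm³ culture well); fiber-tip power density divides power by the
core cross-section (76 mW/mm² for 0.15 mW over 50 μm); photon rate uses
the Planck relation E = hc/λ.  Microchannel flow uses the rectangular-duct
hydraulic resistance R = 12 μL/(w h³ (1 − 0.63 h/w)), valid for h ≤ w;
the effective fluidic path (on-chip plus interface tubing) is exposed as
parameters rather than fixed, because predicted flow depends on it
directly.

## Synthetic preparation

The generator (`synth`) is the package's study condition: a desk-scale
stand-in for a 4 × 10⁷ cells/mL culture, sized so the per-electrode
statistics are realistic while simulations stay interactive.

**Populations.** Two somatic boxes of 1000 neurons each flank a cell-free
neurite corridor (`single_group=True` instead places the 2000 neurons
uniformly — the preparation used for the spontaneous-maturation
analyses).  80 % of neurons express ChR2 (broad viral infection).

**Maturation.** A logistic factor m(DIV) centred at DIV 10 (steepness
1 day) scales connection probability, firing rates, burst rates, burst
recruitment radius, and the fraction of neurons that fire at all
(15 % → 100 %).  The centring reflects the surge of synapse formation
after day 10 in these cultures.

**Connectivity.** P(i→j) = p₀ exp(−d/λ) m(DIV) with p₀ = 0.3 and
λ = 150 μm; inter-region axons route straight through the corridor.  Each
synapse's delay is the conduction time d/v (axonal velocity v = 500 mm/s)
plus one uniform draw from the 1–4 ms single-synapse latency band.

**Spontaneous activity.** Firing neurons emit homogeneous Poisson spikes
at 0.02–0.5 Hz (immature → mature) plus network bursts: events arise at
0.02–0.35 /s, recruit neurons within a DIV-dependent radius
(200 → 2500 μm) with probability 0.8, and each participant emits a
jittered copy (σ = 1.5 ms) of a shared 3–10-spike skeleton with
intra-burst intervals of 10–80 ms.  The mature balance deliberately puts
most spikes inside bursts, as in synchronized mature cultures; this is
what carries electrode-pair synchrony above the 0.5 link threshold.
A 2 ms refractory period is enforced everywhere.

**Optogenetic cascades.** At each light onset, illuminated ChR2 neurons
fire after a 1–3 ms uniform activation jitter and continue firing at 8 Hz
for the duration of the 2.5 s pulse (sustained photocurrent).  Every spike
triggers each outgoing synapse with probability 0.3 after the edge's
delay; a per-pulse cap of 12 spikes per neuron (synaptic depression)
bounds reverberation.  No evoked spike ever precedes its trigger.
The 1–3 ms activation jitter is chosen so that near-site evoked latencies
sit at the lower edge of the observed 2–8 ms band; at 76 mW/mm² the
channel opens quickly.

**Pharmacology.** CNQX/AP5 zeroes transmission at excitatory synapses;
intrinsic tonic firing persists but network bursts — which are mediated by
excitatory transmission — disappear.  TTX silences all spiking.  Both
return modified copies, so wash-out is the original object.

**Electrode pickup.** A neuron contributes spikes to every electrode
within 50 μm (just above half the 85 μm pitch; adjacent sites share ~1 %
of units, so synchrony reflects the network rather than shared pickup),
with amplitude decaying as amp/(1 + (d/100 μm)²) from a 150–300 μV somatic
peak.  Electrodes in the neurite region additionally sense axons of
cross-region projections passing within the pickup radius, at half
amplitude and delayed by the conduction time to the closest axonal point —
so neurite-region signals appear only once inter-region connectivity
exists, as observed in maturing preparations.  Raw traces insert a
biphasic ~1 ms template per spike on Gaussian noise of σ = 16.7 μV
(3 × noise ≈ 50 μV) at 20 kS/s.

**Velocity-recovery scenario.** `velocity_scenario` builds synaptic chains
from a ChR2 neuron at the stimulation electrode to one target neuron near
every electrode on the stimulation row (longitudinal, n = 19) and column
(transverse, n = 7).  Each target soma is displaced up to 25 μm from its
electrode; the chain's total delay is 1 ms + (soma distance)/v(direction)
plus a 0.02 ms dispersion, decomposed into equal per-hop delays within the
1–4 ms band.  Putting the dominant scatter in the soma-to-electrode offset
places the regression noise in the distance (response) axis, so the
ordinary-least-squares confidence interval is correctly calibrated; noise
in the latency (predictor) axis would bias the slope (errors-in-variables
attenuation).  Relay neurons sit at z = 140 μm, at least 45 μm from any
electrode, so recorded first-spike latencies realize exactly the injected
travel times.  Default injected velocities are 500 mm/s longitudinal and
250 mm/s transverse (a 2:1 ratio; the faster longitudinal propagation
reflects the synapse-sparse neurite corridor, where a signal crosses few
synapses per millimetre).

**Determinism.** Every stage draws from a named substream of the master
seed (SeedSequence over a CRC of the stage name), so identical configs are
bit-identical and adding one stage never perturbs another.

## Spike detection

Zero-phase 4th-order Butterworth band-pass (300 Hz–6 kHz via forward-
backward second-order sections) precedes detection; zero-phase filtering
avoids the group-delay bias a causal filter would add to evoked-latency
estimates.  Noise is estimated as median(|x|)/0.6745 (MAD), robust to
spike contamination that inflates the raw standard deviation.  Events are
negative crossings of 3 × noise (≈50 μV at the default noise floor),
timestamped at the trough, with a 1 ms dead time.  SNR is mean trough
amplitude over noise σ.  Note the physics of a 3σ threshold: the −3σ
crossing rate of band-limited Gaussian noise is ν₀ exp(−9/2) ≈ tens of Hz
(Rice formula), so per-electrode threshold detection at this multiplier is
a multi-unit, high-sensitivity regime, not a low-false-positive one; the
recovery guarantee tested is ≥95 % recall of true spikes at default
amplitudes.  No spike sorting is performed — the downstream analyses are
per-electrode (multi-unit) throughout.

## Activity metrics

Bursts are maximal runs of consecutive spikes with all inter-spike
intervals ≤ 0.1 s, kept at ≥3 spikes.  Burst statistics report rate,
duration, spikes/burst, mean intra-burst ISI, inter-burst interval
(end-to-next-start; configurable, undefined below two bursts and signalled
as NaN, not an error) and % burst spikes.  An electrode is "active" with
≥5 spikes per session (the cutoff is a package choice; it excludes
noise-only channels and is configurable).

## Synchronization networks

SPIKE-synchronization: spike i of train A is coincident when a spike of B
lies within τ = ½ min of the four adjacent inter-spike intervals (A's
previous/next, and the two around the nearest B spike); the score is total
coincident spikes over total spikes.  Edge spikes draw τ from the
remaining defined intervals; two single-spike trains count as coincident
(unbounded window).  Conventions: both trains empty → 1.0; exactly one
empty → 0.0.  Because of the empty-train convention, and because the
adaptive windows of very sparse trains are wide, graph construction should
be restricted to active electrodes (`build_graph(..., include=...)`); the
pipeline does this.

Electrode pairs scoring strictly above 0.5 form a weighted graph (weight =
score).  Louvain community detection is implemented in-package: greedy
local moves in a seeded visit order (ties broken toward the lowest
community label, isolation allowed when every merge is unprofitable),
alternating with community aggregation until modularity stops improving,
restarted 20 times with different visit orders and keeping the best — a
standard mitigation of the heuristic's local optima; everything is
deterministic under the seed.  On small community-structured graphs the
result matches exhaustive modularity search; on weak-structure noise
graphs any Louvain (including the networkx reference) can stop at a local
optimum — a known property of the algorithm, not of this implementation.
A "network" is a community of ≥2 electrodes; normalized degree is
degree/(N−1).

## Stimulation response and latency

Epoch rates count spikes in each 2.5 s on-interval and the following
off-interval of the 0.2 Hz protocol (six trials by default); on/off
comparisons use the two-tailed unpaired t-test (degenerate zero-variance
inputs return p = 1 when means agree).  Rate-increase maps average the
per-electrode on-minus-off difference per shank, flagging spikeless
electrodes as no-signal.  Evoked latency is the first spike in
(onset + 1 ms, onset + 50 ms] — the 1 ms blank removes the photovoltaic
stimulation artifact — averaged over responding trials; electrodes with no
response are undefined and excluded from maps and fits.  First-spike
rather than burst-centre timing matches the transient onset the latency
analysis reads.

## Transmission velocity

Ordinary least squares of distance (mm, response) on latency (s,
predictor) — the orientation follows the analysis' axis convention, and
the slope is the velocity in mm/s with a 95 % t-interval from the slope
standard error.  Direction classification uses a tolerance of half the
smaller array pitch (180 μm), since exact y = 0 / x = 0 planes never hold
off-grid.  The directional t-test compares per-electrode implied
velocities (distance/latency) between groups.

## Photon transport

Photon packets launch uniformly over the fiber core disk with directions
uniform in solid angle within the 21.9° cone, take free paths
s = −ln ξ/μt, deposit weight via the collision estimator
Φ = Σw/(μt V_voxel) (equal to the absorption estimator for μa > 0 and
still defined at μa = 0), scatter by Henyey–Greenstein inversion
(mean cosine g; g = 0 is isotropic), and undergo Russian roulette below
weight 10⁻⁴ with survival 0.1.  The energy ledger
absorbed + escaped + roulette-killed − roulette-boosted equals the
launched weight to machine precision on every run.  Grid boundaries are
absorbing (escape); refractive-index mismatch is ignored and the
fiber–medium interface treated as index-matched.  The default grid is
383 × 250 × 120 voxels at 3 μm — the voxel edge chosen so the domain spans
the ~1.15 mm collagen scale of the simulated construct.  The axial profile
averages fluence over voxels within the core radius of the source axis;
the threshold depth is the contiguous suprathreshold run from the fiber
face.  With the collagen parameters (μa 0.3 /mm, μs 29 /mm, g 0.89) and
10⁶ packets, the on-axis irradiance stays above the 1 mW/mm² ChR2
threshold beyond 300 μm, and the suprathreshold volume stays laterally
well inside the 360 μm shank pitch (local stimulation).  Packet count is
an accuracy knob; threshold depth varies by <5 % between seeds at the
default count.

## Problem sizes used by the test suite

The suite exercises the generator at 300 s recordings across DIV 6–14
(2000 neurons), 10⁶-packet transport runs, and 100 seeded
velocity-recovery repetitions — sizes chosen so the full chain remains
demonstrably correct while a complete run stays within a coffee break.

## Known limitations

- The generator is phenomenological: no membrane biophysics, no
  inhibition (all synapses excitatory), no plasticity beyond the DIV
  schedule, no astrocytes.  Network bursts are imposed (skeleton +
  recruitment radius) rather than emerging from the synapse graph, so
  burst statistics validate the *metrics*, not burst genesis.
- Passing qualitative tests on this preparation shows the analysis chain
  recovers what the generator encodes; it cannot certify performance on
  biological recordings, whose empirical values (firing rates, velocities,
  latency maxima) are preparation-specific.
- Electrode pickup is a sphere with a smooth amplitude decay; real
  extracellular fields are dipolar and anisotropic.
- SPIKE-synchronization on very sparse trains has wide adaptive windows;
  scores between near-silent electrodes are not meaningful, which is why
  the network stage filters to active electrodes first.
- The photon transport is single-wavelength, time-independent,
  unpolarized, and homogeneous; shank shadowing and the culture-well
  boundary are not modelled.
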