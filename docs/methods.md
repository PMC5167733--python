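# Methods

`somadcm` asks a routing question about the somatosensory system: does
tactile information reach the secondary somatosensory cortex (SII) only
serially, via the primary somatosensory cortex (SI), or also in parallel,
directly from the thalamus — and does the dominant route change over
peri-stimulus time?  The package implements the full inference chain —
biophysical forward model, sensor observation model, preprocessing,
variational Bayesian inversion, and group-level model selection — and
exercises it on synthetic multi-subject MEG-like data with known ground
truth, so that every stage is testable without access to recordings.

## Network and neural-mass model

Three cortical sources are modelled: contralateral SI (SIc), contralateral
SII (SIIc) and ipsilateral SII (SIIi), at fixed canonical locations
(MNI −57/−19/49, −48/−28/16, 51/−25/19 mm).  Extrinsic connectivity is the
same in every candidate model: reciprocal (forward + backward) connections
SIc↔SIIc and SIIc↔SIIi, and a self-connection gain per node.  Each node is
a three-subpopulation evoked-response neural-mass model (spiny-stellate,
pyramidal, inhibitory-interneuron populations).  Every synapse applies a
second-order kernel

    v̈ = (H/τ)·σ(input) − (2/τ)·v̇ − v/τ²,

and populations communicate through a centred sigmoid firing function
σ(v) = f·(1/(1+e^{−rv}) − ½) with slope r (per mV) and maximal rate f.
Forward connections and thalamic drive enter the granular (stellate)
population; backward connections enter the pyramidal and inhibitory
populations; the measured source signal is the pyramidal depolarization.
Inter-node influences are conducted with a 16 ms delay and intrinsic
recurrent firing with a 2 ms delay, implemented by linear interpolation of
the stored solution history.

Defaults (all are prior means, re-estimated during inversion):

| parameter | value | meaning |
|---|---|---|
| H_e, H_i | 3.25, 29.4 mV | excitatory / inhibitory synaptic gain |
| τ_e, τ_i | 10, 16 ms | synaptic time constants |
| γ₁..γ₄ | 50, 40, 12, 12 | intrinsic coupling |
| r | 0.56 /mV | sigmoid slope |
| f | 0.005 /ms | maximal population firing rate (2·e₀) |
| input gain | 0.1 | firing-equivalent scale of the thalamic drive |
| delays | 16 / 2 ms | extrinsic / intrinsic conduction |

The firing-rate ceiling f and the drive gain follow the classical
evoked-response parameterization in which population firing saturates at a
few spikes per millisecond-equivalent units; together with the γ values
above this places the network in the damped, weakly nonlinear regime that
evoked responses occupy (impulse responses decay; no autonomous
oscillation).  Self-connections are realized as one multiplicative gain per
node on all four intrinsic couplings, estimated on the log scale.

Integration is fixed-step RK4 at 0.5 ms, sampled onto the requested grid.
Halving the step changes the solution by ~1e−5 RMS, two orders below every
tolerance used in testing.  Divergence (non-finite or >1e6 state values)
raises an error naming the parameter regime.

## Thalamic input and the four architectures

Thalamic drive is not a dynamical node; it is one or two Gaussian input
functions of peri-stimulus time: a **phasic** component (mean 30 ms,
SD 16 ms) encoding stimulus onset and a **sustained** component (mean
170 ms, SD 70 ms) for the ongoing 260 ms stimulation.  The four candidate
architectures differ only in where these inputs enter:

* **A** serial throughout — both components to SIc only;
* **B** serial→parallel — phasic to SIc; sustained to SIc + SIIc;
* **C** parallel→serial — phasic to SIc + SIIc; sustained to SIc;
* **D** parallel throughout — both components to SIc + SIIc.

SIIi never receives direct input.  Phasic and sustained components have
independent amplitudes per target (the superset of the possibilities; a
shared amplitude is a special case).

## Observation model and preprocessing

Each source projects to the sensors through one gain column.  Real lead
fields need individual anatomy, which is out of scope; instead each node
gets a smooth synthetic topography exp(−d²/2w²) (angular distance d from
the sensor nearest the node's MNI direction, width w = 0.5 rad) on a
deterministic 102-channel unit-hemisphere layout, with a seeded 5%
multiplicative jitter standing in for between-subject lead-field
variability.  This preserves what matters for the inversion — overlapping,
node-specific spatial mixing — without a head model.

Preprocessing follows standard evoked-field practice: zero-phase 4th-order
Butterworth band-pass 0.5–100 Hz (forward–backward), decimation from 2 kHz
to 500 Hz (the 100 Hz low-pass is the anti-alias filter), epoching over the
closed interval [−50, 300] ms around the (onset-corrected) stimulus markers
— 176 samples per epoch — and baseline correction over the half-open
pre-stimulus window [−50, 0) ms.  Stereotyped artifacts are removed by
signal-space projection: the leading principal component of the
concatenated segments around each labelled artifact event gives one
topography per artifact class, and the data are projected onto the
orthogonal complement of their joint span (rank reduction exactly one per
independent class).  Visual trial rejection is replaced by an automatic
amplitude criterion (peak z-score > 6, logged).

Before inversion the trial-averaged ERF is restricted to an analysis window
and reduced to its 7 leading spatial modes (left singular vectors),
computed per subject and per window; windowed mode-space data are scaled to
unit RMS, with the reduced gain carrying the same factor.

## Variational inversion

For one subject, model m and window w, the reduced data Y (modes × samples)
are modelled as Y = g(θ) + ε with g the simulated source activity passed
through the reduced gain and ε Gaussian with one precision hyperparameter
per spatial mode (IID in time).  Parameters θ are: log-scaling coefficients
on the four extrinsic connections (prior SD 0.25), on the three
self-connection gains (SD 0.125) and on each gated input amplitude
(SD 0.5); plus, where timing is estimated, an additive onset-mean shift
(prior SD 8 ms phasic / 35 ms sustained — half the input SDs, keeping the
onsets near their nominal roles) and a log-scale on the onset SD (SD 0.2).

The scheme is standard variational Laplace: a Gauss-Newton outer loop on θ
(finite-difference Jacobians), a Newton update of the log noise precisions
given the expected residual sum including the posterior-uncertainty trace
term, Levenberg-Marquardt damping with step rejection, and the free energy

    F = ⟨log p(Y|θ,λ)⟩_q − KL(q(θ)‖p(θ)) − KL(q(λ)‖p(λ))
      = accuracy − complexity

as the convergence criterion (tol 0.01 nats, max 64–128 iterations) and the
model-evidence approximation.  F is monotone over accepted iterations by
construction; a stall under heavy damping is a converged maximum.  On a
linear-Gaussian problem with pinned noise the scheme reproduces the
conjugate posterior and log evidence to ~1e−12, which the test suite
asserts at 1e−3 nats.

Because the ascent is local, inversion restarts once from shrunk input
amplitudes (log-scale −1) whenever any of the three leading modes retains
more than half its variance after the first fit.  This matters for short
late windows, where the evoked tail is weak and a greedy first step can
inflate amplitudes into a poor basin.

The simplified stimulus-initiation models (serial vs parallel deployment of
the phasic input alone) use the same inverter with input timing fixed at
the prior: the two models are meant to share one stimulus-onset input, and
freeing its onset/width would let the "onset" input morph into a surrogate
sustained drive and confound the routing comparison.

## Window schemes

Two schemes cover the two complementary analyses: (i) incremental windows,
all starting 1 ms post-onset, lengths evenly spaced 40→260 ms snapped to
the 2 ms sample grid (18 for the four-model analysis; 10 for the
initiation analysis) — the exact length set is not uniquely determined by
the source material, so even spacing is adopted and config-overridable;
(ii) fixed-length 60 ms windows stepped across the epoch (default step
30 ms, also not uniquely determined).  Windows are closed intervals on the
500 Hz grid; (1, 40) contains 20 samples.

## Group inference

Per window, subjects' free energies enter random-effects Bayesian model
selection: the variational Dirichlet scheme over model frequencies
(u_nk ∝ exp(F_nk + ψ(α_k) − ψ(Σα)); α = α₀ + Σ_n g_nk, α₀ = 1), iterated to
‖Δα‖ < 1e−6.  Exceedance probabilities — the probability that a model is
the most frequent in the population — use the exact Beta tail for two
models and seeded Monte Carlo (1e6 draws, argmax partition, sums to one
exactly) otherwise.  Note the single-subject ceiling: one subject, however
decisive, yields α = (1, 2) and EP = 0.75.

Bayesian model averaging of input strengths defaults to the group-level
winning model (one-hot weights), with per-subject softmax weighting as an
option; the summed per-target amplitudes (natural scale) of SIc vs SIIc are
contrasted by a paired two-sided t-test (df = subjects − 1).

## Synthetic data generator

The generator encodes the study conditions: 17 subjects, 154 trials per
subject, inter-stimulus intervals uniform in 2–3.8 s, 260 ms stimulation,
2 kHz acquisition, 102 channels.  Event markers carry the +40 ms pneumatic
onset correction, i.e. they mark true tactile onset.  Per subject, the
group-mean network is perturbed log-normally (SD 0.2 on connection gains
and input amplitudes — a conventional moderate between-subject dispersion)
and sensor noise is AR(1) in time (coefficient 0.95 at 2 kHz, a crude 1/f
surrogate), IID across channels, scaled so that SNR — the ratio of the
noiseless trial-averaged ERF RMS to the single-trial noise RMS over
post-stimulus samples — equals the requested value (default 5).  Optional
cardiac (1 Hz periodic) and ocular (Poisson) artifacts are injected with
fixed random topographies at per-channel amplitudes of ~10–20 noise SDs,
matching the dominance of physiological artifacts over evoked fields.
Phasic and sustained group-mean amplitudes are equal by default (the
neutral choice absent amplitude measurements); per-target gains are
configurable (the input-contrast analysis halves the SIIc gain).

A fast epoch-level path generates 500 Hz epochs directly — identical
evoked signal, AR(1) noise with the coefficient raised to the decimation
factor — and is what the large recovery analyses use; the continuous 2 kHz
path (filtering, decimation, epoching, SSP) is exercised on smaller
problems.  What the generator does **not** emulate: realistic head
geometry and lead-field correlations, environmental interference,
head movement, channel-type mixing, and trial-to-trial variability of the
evoked response itself.  Passing recovery tests therefore demonstrate that
the inference machinery is correct and well-calibrated under the model
class, not that real MEG data would be as decisive.

## Problem sizes and reproducibility

The recovery analyses run at the full group size (17 subjects, 154 trials,
SNR 5).  The four-model architecture recovery uses the full 1–260 ms
window with three replicates per ground-truth architecture; the initiation
analysis uses eight fixed 60 ms windows (starts 0–210 ms); the
input-strength contrast uses ten replicate groups.  All randomness flows
from explicit seeds (group seeds spawn per-subject seeds), inversions are
deterministic, and Monte-Carlo exceedance is seeded, so every reported
number is bit-reproducible.

## Known limitations

* In fixed windows starting beyond ~200 ms the phasic-only initiation
  models explain almost no variance (their only input peaked at 30 ms), and
  model comparison there is driven by residual-fitting flexibility rather
  than routing: the extra direct-SII input lets the parallel model absorb
  unmodelled sustained activity, so the serial dominance seen in the
  120–240 ms windows reverts.  The initiation analysis is therefore
  informative about the switch location, not about the farthest windows.
* Free energies from a near-noiseless trial average (effective ERF SNR
  ≈ 5·√154) are large in magnitude; model comparisons are meaningful as
  differences, not absolute values.
* The synthetic gain model makes spatial separation of SIc and SIIc easier
  than real anatomy would; recovery rates on real data would be lower.
* Nonlinear multimodality of the free-energy surface is handled with one
  deterministic restart, not a global search.
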