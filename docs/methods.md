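# Methods

`smfretkin` analyzes camera-based single-molecule FRET recordings of a
molecule that interconverts among a small number of conformations — the
motivating system is the uranyl-specific DNAzyme 39E, whose enzyme and
substrate strands place a Cy3/Cy5 pair so that four conformations are
distinguishable by their FRET efficiency: native (N, E ≈ 0.25), folded
(F, ≈ 0.47), compact (C, ≈ 0.58), and extended (E, ≈ 0.12).  The package
covers the whole chain from raw two-channel intensity traces to
per-transition rate constants and a free-energy landscape, together with a
generator of synthetic data that provides ground truth for every stage.

## Model and assumptions

Conformational dynamics are modeled as a continuous-time Markov chain
(CTMC) with first-order rate constants `k_ij` between labeled states.  The
camera integrates the trajectory into frames of period Δ (default 50 ms);
the observable per frame is the proximity ratio `E = I_A / (I_A + I_D)`,
with no background, crosstalk, or gamma correction (the two channels enter
only as a ratio, so intensity units are arbitrary).  Within one state the
frame-to-frame spread of E is taken Gaussian.  The assumptions that matter:

* switching is memoryless (exponential dwell times, one rate per ordered
  state pair);
* emission is one Gaussian per state on the E axis; a frame that straddles
  a switch carries the time-weighted average of the two state means;
* photobleaching truncates the usable signal but does not otherwise
  interact with the dynamics.

## Synthetic data generator

`synth` samples CTMC paths exactly (Gillespie: exponential waiting times
with the total exit rate, successors proportional to `k_ij`) and renders
them to frames.  The noiseless frame value is the *exact* time integral of
the state means across the frame (computed from the running integral of
the piecewise-constant path, so mid-frame switches produce the correct
intermediate values; the `substeps_per_frame` knob is retained for
interface compatibility but no discretized approximation is involved).
One Gaussian "state jitter" per frame (occupancy-weighted `sd_E`) models
conformational and photophysical broadening; channel intensities are
`acceptor = E·I_T + noise`, `donor = (1−E)·I_T + noise` with a per-trace
total intensity `I_T`.

Experiment-level structure mirrors flow-cell injection assays: molecules
evolve under a pre-injection scheme; with probability `responder_fraction`
a molecule switches to the post-injection scheme after an optional
exponential delay.  Donor/acceptor photobleaching are independent
exponential clocks.  Shipped schemes carry the published kinetic
parameters of the system: `Mg30` (F↔C at 0.67/7.24 s⁻¹, F↔E at
0.015/0.19 s⁻¹; C↔E set to 0 because too few events exist to quantify it),
`NoDivalent` (N↔C at 0.36/2.74 s⁻¹, N↔E at 0.33/0.58 s⁻¹), `UO2`
(extension to E ≈ 0.11), and `Native` (static N).

Parameters the source experiments do not pin down are fixed once at
realistic values and never tuned: per-state emission SD `sd_E = 0.05`
(typical smFRET histogram width), total intensity 500 ± 50 camera units
per frame, additive channel noise SD 10.  Together these give a per-frame
E noise of ≈ 0.052.  What the generator deliberately does *not* emulate:
Poisson/EMCCD excess noise, spectral crosstalk and gamma factors, drift,
multi-molecule spots, non-Markovian dynamics.  Passing tests therefore
demonstrate correctness of the analysis chain under the stated model, not
robustness to every artifact of real recordings.

## Preprocessing

`compute_efret` masks frames whose total intensity falls below 10% of the
pre-bleach median (guards 0/0 after bleaching), frames inside the
direct-acceptor-excitation window, and frames at/after detected bleaches;
E is not clamped to [0, 1].  Bleach detection is a running-median step
detector: donor bleach = first frame after which the smoothed total stays
below `baseline_fraction` (0.25) of the bright-phase level for at least
`persistence` (10) frames; acceptor bleach is the analogous single-channel
drop with an anticorrelated donor rise.  On synthetic truth the detector
locates forced bleaches within ±2 frames.

Response classification compares median E in a pre-injection window with
the tail of the post segment against the canonical levels (`fold` toward
F, `extend` toward E, with a minimum shift of 0.1 — half the smallest
inter-level gap); `dynamic` requires ≥ 2 idealized switches after
injection.  The injection-to-response delay is the time to the first
*sustained* (one persistence window) occupancy of the destination level;
a single median crossing proved noise-sensitive (~3% false onsets), the
sustained-run rule removes the resulting bias.

## Idealization

A single global Gaussian-emission HMM per condition is fitted by
Baum–Welch over all molecules' valid segments jointly — pooling matches
per-condition rate reporting and stabilizes rare states — and each
molecule is decoded with Viterbi.  Numerics: scaled forward–backward
(equivalent to log-space, but batchable); segments are right-padded with
unit emission likelihood, which provably leaves every scaled quantity
unchanged, so the whole data set is one `(segments × T)` batch.  Invalid
frames break the chain and decoding restarts from the initial
distribution.  Variance floor 1e-6 E²; EM stops at relative log-likelihood
improvement < 1e-6.

Initialization is deterministic hierarchical splitting: fit one state in
closed form, then repeatedly split the state with the largest
occupancy-weighted variance (means ± SD/2) and refit until K states.
Histogram-mode seeding was tried first and rejected: a minority state
whose level sits on the shoulder of a dominant state (C at 0.58 next to F
at 0.47) is not a mode of the pooled histogram, and EM started from modes
merges the pair.  Model-order selection uses BIC with
p = K² + 2K − 1 parameters.  Fitted states are labeled by the nearest
canonical level (tolerance 0.08; ambiguity is an error, distant states
become "other").  When injection metadata exists the pipeline idealizes
the post-injection phase, whose kinetics the conditions define; the static
pre phase is summarized by the response call.

## Dwell times and rates

Maximal constant-label runs become dwells; runs shorter than
`min_frames = 2` (100 ms) are flicker-suppressed (removed, same-labeled
neighbors merged).  Dwells abutting a trace boundary, mask gap, injection
split, or bleach are censored on that side.

Rate fitting is dwell-based.  For a single state, the single-exponential
MLE is the reciprocal mean of complete dwells (`fit_exponential`, with a
Freedman–Diaconis histogram least-squares variant for parity, and a
by-molecule bootstrap CI).  `build_rate_table` splits each state's total
exit rate among destinations by branching fractions and handles two biases
that matter at 50 ms resolution:

1. *Discretization*: dwells are measured in whole frames, so frame counts
   of a sampled chain are geometric, not exponential.  The fit uses the
   censored geometric MLE above a dead time equal to `min_frames`
   (memorylessness makes the shifted counts the same geometric law);
   right-censored dwells enter through their survival term, since dropping
   them length-biases states whose dwells are comparable to the recording
   (measured +15% on a 5 s state in 100 s traces).
2. *Missed events*: sojourns near the frame time are absorbed into their
   neighbors by any decoder.  Closed-form corrections (destination
   detection probability, invisible round trips) are applied, but the
   decoder's actual behavior at ~2σ emission separation is not
   truncation-like, so `self_calibrate_rates` measures the bias directly:
   synthetic segments matching the observed segment lengths are generated
   from the *fitted* emission model at the current rate estimates, pushed
   through the identical fit/decode/count chain, and each rate is rescaled
   by observed/simulated; two fixed-point rounds converge.  This is the
   simulation analogue of the missed-event corrections standard in
   single-channel electrophysiology and uses no information beyond the
   observed data and fitted model.

On synthetic data at the published parameters (500 traces × 2000 frames),
all non-excluded rates are recovered within ±9% across seeds, including a
7.24 s⁻¹ rate whose mean dwell is 2.8 frames; the uncalibrated estimator
underestimates that pair by ~30–45%, which is why the calibration is on by
default.  The slowest rate (0.015 s⁻¹) is validated on 60 recordings of
20,000 frames, fitted on 2000-frame chunks (a well-shaped EM batch) and
decoded full-length.

Rate classes observed in fewer than `min_molecules = 20` molecules are
reported but excluded from fitting, mirroring the practice of dropping
transition classes seen in only a handful of traces.

Transition summaries: the TDP weights every transition event once at
(E before, E after) and is normalized to total count; the TODP weights
each *molecule* once per unordered transition class — the fraction of
molecules exhibiting the class — so hyperactive molecules cannot dominate.
Default grid 0.02 E units over [0, 1]², fine enough to separate the four
levels.

## Energies and distances

Activation energies invert the Arrhenius relation,
`E_a = RT (ln A − ln k)` with A = 10³ s⁻¹, R = 8.31 J/(K·mol), T = 297 K.
A is an order-of-magnitude convention: absolute barriers shift by
`RT ln A`, while well-depth differences `ΔG(i→j) = RT ln(k_ji/k_ij)` are
prefactor-free and are the meaningful output.  A landscape accumulates
well energies along a state ordering (default E–N/F–C), anchors the
deepest well at 0, and reports barriers above the departure well; the
construction guarantees `barrier(i→j) − barrier(j→i) = well(j) − well(i)`.
Mean donor–acceptor distances use `r = R0 (1/E − 1)^(1/6)` with a
configurable Förster radius (default 5.4 nm, a common literature value for
Cy3/Cy5 — an assumption, not a measured quantity).

## Degenerate inputs and tie-breaks

Absorbing states yield single-segment paths; all-masked traces produce
empty E series and all-invalid idealized paths; a state capturing < 1
expected frame aborts the fit with a suggestion to lower K; equal-distance
level labeling resolves to the first nearest level in dictionary order;
blips whose two neighbors disagree become censoring gaps rather than
inventing a direct transition.

## Known limitations

* The calibration inherits the fitted model's quality: misspecified
  emissions (non-Gaussian noise, level drift) propagate into the
  correction on real data.
* Rates much faster than ~1/(2Δ) remain unidentifiable regardless of
  correction; the calibration clips per-round factors at 3× as a guard.
* Dwell-time fits assume single-exponential kinetics; multi-exponential
  dwells (hidden substates) are out of scope.
* The TODP denominators use all molecules passed in, not a per-class
  eligibility count.
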