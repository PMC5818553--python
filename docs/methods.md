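# Methods

## Scope

`gcampflux` has two halves.  The *analysis* half (`extract`, `kinetics`,
`classify`, `coloc`, `report`) quantifies bouton-level GCaMP recordings:
background-subtracted ΔF/F traces, baseline and noise statistics, responder
gating, peak/half-rise/half-decay kinetics, waveform taxonomy, two-channel
mitochondrial occupancy, and grouped statistics.  The *simulation* half
(`simulate`, `scenarios`) is a forward model from stimulus protocol to
noisy movie with complete ground truth, so that each analysis stage can be
tested as a parameter-recovery problem.

## Forward model

**Spikes.**  A stimulus train of frequency f and duration T delivers
⌊fT⌋ pulses starting at the onset time.  Each pulse triggers either one
axonal action potential, a burst of `aps_per_stimulus` events spaced at
1/`burst_rate` (supernumerary firing under hyperexcitability), or nothing
if the previous event lies within `failure_recovery_time` of the pulse
(conduction failure of a refractory axon; a gap exactly equal to the
recovery time delivers, with a 1 ns float tolerance).  Post-train rebound
firing is a regular burst beginning `rebound_delay` after train end.
Explicit per-pulse delivery patterns can be injected to construct
ground-truth waveform scenarios (terminal blocks, alternating blocks).

**Calcium.**  A single well-mixed compartment:

dCa/dt = −k_leak·(Ca−Ca_rest) − s(t)·V_max·(Ca−Ca_rest)/((Ca−Ca_rest)+K_m) + δ_AP·Σδ(t−t_i)

Each AP adds δ_AP nM instantaneously.  Clearance is a passive leak plus a
saturable pump; the schedule s(t) ∈ [0,1] scales pump capacity over
*experiment* time (constant 0.6 for high-pH PMCA suppression; linear
rundown to 0 over 60 min for mitochondrial uncoupling, with the incubation
offset passed per trial).  Integration: when V_max = 0 the solution is the
exact superposition of decaying exponentials (vectorised); otherwise
classical RK4 between grid nodes with exact event splitting, on a grid 10×
finer than the frame rate.  RK4 at this step size agrees with a 10×-finer
explicit-Euler oracle to well under 1% (test-pinned).

**Indicator.**  Hill binding θ = Ca^n/(Ca^n+K_d^n), optionally relaxed
toward the quasi-static value with first-order time constant
`binding_tau` (exact exponential update per step, so a concentration step
gives the textbook 1−e^(−t/τ) response).  ΔF/F = R_max(θ−θ_rest)/(1+R_max·θ_rest)
with θ_rest computed from Ca_rest, the same convention the extractor
measures; the analytic saturation ceiling R_max(1−θ_rest)/(1+R_max·θ_rest)
is never exceeded.  Published constants: GCaMP1.3 K_d 234 nM / n 3.3,
GCaMP6m 167 nM / 2.96, myrGCaMP5 447 nM (Hill coefficient unpublished;
3.3 used as a family placeholder).  R_max and binding_tau are package
defaults, not measured values.

**Rendering.**  Frame values are exposure means of the fine-grid ΔF/F
(frames timestamped at exposure midpoints).  A bouton is a radially
tapered disk, w(r) = 1−(r/radius)², pixel value
background + Σ_b f0_b·w_b·(1+ΔF/F_b(t)), plus i.i.d. Gaussian read noise
(σ configurable; deterministic per `rng_seed`).  Additive Gaussian rather
than Poisson noise: the analysis consumes only the RMS noise level.
Because ΔF/F is a ratio, the taper factor cancels and noiseless extraction
reproduces ground truth to machine precision.  Two-channel pairs render
static boutons (green) and punctate mitochondria inside occupied boutons
(red) with a per-bouton truth table.  Focal-electrode records are
biexponential deflections (rise τ/5, decay τ) peak-aligned to AP times at
≥ 10/τ sampling.

## Analysis conventions

* Baseline window: the last 25 frames strictly before stimulation onset
  (1 s at 25 Hz); the onset frame is excluded.
* N_B is the RMS of baseline ΔF/F deviations (equivalently SD of baseline
  F_t divided by F_B).  Taken literally on raw F_t an "RMS of the
  baseline" would approximately equal F_B itself and a 200%-of-noise gate
  would be meaningless; the ΔF/F reading makes the gate dimensionally
  consistent with max ΔF/F.
* Background subtraction is per-frame (robust to lamp drift); the
  background region is a fixed rectangle adjacent to the bouton, not a
  morphological estimate.
* Responder rule: max ΔF/F (smoothed) strictly greater than 2 N_B.
  Nonresponders carry NaN kinetics and are excluded from kinetic means.
* Smoothing: centred 5-point running mean, truncated windows at the edges
  (3 points at the ends).  max ΔF/F is searched in [onset, onset+2 s],
  ties to the earliest frame.
* Threshold crossings use linear interpolation between frames and must
  hold for 2 consecutive frames.  The persistence requirement exists
  because a strict earliest-crossing rule is biased early by noise dips on
  slowly decaying traces (at SNR 10 and t_1/2 ≈ 1.4 s the median error
  reaches −0.07 s, outside the one-frame recovery tolerance the estimator
  is designed for); with it, disjoint 100-seed medians sit within ±0.034 s
  of ln 2/k for k ∈ [0.5, 4] s⁻¹.  On noiseless monotone traces the rule
  is identical to earliest-crossing.  Note the 100-seed median at
  k = 0.5 s⁻¹ still carries a sampling σ of ≈ 0.02 s, so occasional seed
  draws fall just outside one frame interval.
* Half-decay reference: the smoothed trace value at train end, not
  max ΔF/F — intermittent traces can peak well before the train ends; the
  two coincide for the usual monotone rise.  No crossing before record end
  sets `decay_censored` and reports the observable lower bound.
* QC: configurable F_B floor and N_B ceiling (defaults 1.0 intensity units
  and 0.1; the source protocol reports only that such traces were excluded,
  < 5% in total).  Contraction artifacts are a manual-flag passthrough.

## Waveform taxonomy

The source taxonomy (normal / aborted / intermittent / no response, plus
post-train rebound) was applied by eye; the classifier operationalizes it:
no_response if not a responder; otherwise *drop episodes* during the train
are runs (≥ `min_gap` = 3 frames, single-frame interruptions closed) in
which the smoothed trace sits more than `drop_frac` = 30% below its running
peak and more than 1.5 N_B deep, once the running peak has reached 20% of
the in-train maximum.  Any episode that ends before train end means the
trace recovered → intermittent; only a terminal episode → aborted.  After
train end, once the trace falls below 50% of the in-train peak, a renewed
excursion above `rebound_frac` = 50% of the peak plus a 1.5 N_B hysteresis
band flags rebound (replacing only "normal").  All thresholds are
fractional, so labels are invariant to uniform scaling.  On noiseless
scenario-bank traces the classifier recovers ground truth exactly; at
SNR 10 accuracy is 94–98% over 200 runs (residual confusions are
aborted↔intermittent at block boundaries).  The scenario bank uses 10-Hz,
4-s trains so a 10-pulse failure block lasts 1 s — long enough to produce
a visible sag against the type II clearance rate; at 20 Hz a 0.5-s block
is invisible after smoothing, which is a physical property of slow
indicators, not a classifier defect.  Fine-grained periodic failures (the
`para_ts1` recovery rule at high frequency) likewise smooth into
low-amplitude "normal" traces; block-level failures are what the taxonomy
can see.

## Scenario presets

Presets are JSON files resolved against the wild-type base.  The genetic
and pharmacological conditions they name are characterized qualitatively
(which terminal type is affected, burst firing vs conduction failure vs
pump suppression), so preset parameters are illustrative and were tuned
*only* to reproduce ordinal relations: threshold frequencies II (10 Hz) <
Is (20 Hz) < Ib (40 Hz); clearance capacity Ib > Is > II (pump V_max
60/48/21 nM s⁻¹ with K_m 10/15/30 nM, shared leak 0.3 s⁻¹) and per-AP
influx II > Is > Ib (δ_AP 4.0/2.3/1.6 nM), which also place half-decay
times at ≈ 0.35–0.5 s for type I and ≈ 0.8 s for type II terminals.
Ca_rest (50 nM) and δ_AP are placeholders — resting Ca²⁺ and single-AP
increments are not quantified for these terminals — and are flagged as
such in the preset files.  All conduction failures are modeled as delivery
failures at the terminal; whether real failures occur at the branch point
is not modeled.

## Colocalization

Each channel is thresholded independently: Otsu by default for the bouton
channel; a median + 5·MAD rule (`robust`) is provided for the sparse
punctate channel, where Otsu's two-class assumption collapses (~1%
foreground);  absolute and percentile thresholds support reproducibility
pinning.  Boutons are connected components of ≥ 5 pixels (rejecting noise
specks); a bouton is occupied when ≥ `min_overlap_px` = 2 red pixels fall
inside it.  An optional integer-shift registration maximizing mask overlap
replaces manual image merging; the default is the identity.

## Statistics

Bouton grain pools all boutons; NMJ grain averages boutons within a
terminal first and treats terminal means as observations (SEM at the
declared grain; table cells render "mean ± SD (n, N)" at 2 decimals).
Base tests are scipy.stats (Kruskal–Wallis, Student's t, one-way ANOVA);
Fisher's LSD is computed from the pooled ANOVA MSE.  Bonferroni adjustment
is min(1, m·p) over a declared comparison family; stars at 0.05/0.01/0.001.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the recordings (frame rate,
train protocols, baseline windows, bouton footprints, read noise, the
leaky-integrator relation between firing and ΔF/F) but not real-data
nuisances: no motion or muscle-contraction artifacts, no bleaching or lamp
drift, no Poisson photon statistics, no bouton-size variability along a
terminal, no ER compartment.  Passing tests therefore demonstrate that the
analysis recovers known parameters under the stated model, not that the
model captures every property of real NMJ recordings; measured values in
the source literature (Tables of max ΔF/F and kinetics per genotype) are
real-imaging quantities that desk-scale simulation is not expected to
reproduce numerically.

## Problem sizes

Default desk-scale sizes keep the whole suite fast: trace-level runs use
2 NMJs × 6 boutons per terminal type, 8–12 s records at 25 Hz with a 10×
oversampled ODE grid; movie tests render ≤ 100 frames at ≤ 188² pixels;
recovery tests use 100 noise seeds per clearance rate; the classifier bank
uses 200 runs; aggregation oracles use 1000 random tables.
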