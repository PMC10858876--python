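# Methods

This note documents the models, conventions and design choices behind
`periseizure`: what each stage computes, why the defaults are what they
are, and what the synthetic-data generator does and does not emulate.

## Experimental setting being modeled

The package analyzes acute optogenetically induced seizures in freely
behaving mice recorded with simultaneous EEG (1 kHz) and fiber photometry
of hypothalamic hypocretin/orexin neuron (HON) population calcium
(GCaMP6s, dual 465/405 nm excitation, 10 Hz per channel).  Each session
is a 6-minute window centered on one seizure induction: a 10-s
optogenetic stimulation train (5, 10 or 20 Hz) delivered to hippocampal
CA1, followed in successful trials by a seizure-like after-discharge.
Seizure intensity is quantified as EEG band power in the 4–14 Hz band of
interest; HON activity is summarized as the mean corrected photometry
signal in the 60 s before induction (pre-seizure) and during the seizure.

## EEG spectral chain

* **Filtering.** Zero-phase (forward–backward) 4th-order Butterworth
  low-pass at 100 Hz, then a 2nd-order IIR notch at 50 Hz with quality
  factor Q = 30 (−3 dB width ≈ 1.7 Hz).  Zero-phase application squares
  each filter's magnitude response; the quoted orders describe the design.
  Q is a package choice (the notch order is fixed, its bandwidth is not);
  Q = 30 removes line noise without touching the 4–14 Hz band.
* **Welch PSD.** Non-overlapping 1-s Hann-tapered epochs, one-sided
  density normalization (µV²/Hz), no per-epoch detrending.  With a 1-s
  epoch the frequency resolution is 1 Hz.  The integral of the PSD over
  [0, fs/2] equals the window variance (Parseval), which the tests verify
  to 5% on stationary inputs.  Overlap is configurable in principle but 0
  by default; the taper/normalization choice only scales absolute units.
* **Band power.** Trapezoidal integral of the PSD over [4, 14] Hz, units
  µV².  An integral (rather than a per-bin mean) is used because it has
  Parseval-checkable units; the two differ by the constant bin width.
* **Seizure power.** Band power over the half-open window
  [induction, induction + 30 s), which spans the stimulation and the bulk
  of the after-discharge.  All windows are half-open, in seconds from
  recording start.
* **Spectrogram.** The per-epoch periodogram stack; its column average
  reproduces the Welch estimate exactly (same code path), a consistency
  the tests assert at 1e-9 relative.

## Photometry correction

Each channel independently: (1) linear bleach detrend over the 6-minute
analysis window, with the line anchored at the medians of the first and
last 50 s of that window (anchor abscissae at the mean flank time, so an
exactly linear trace is removed exactly); (2) z-scoring by the median and
ordinary SD of the 60 s before induction; (3) the z-scored 405 nm
(isosbestic) trace is subtracted pointwise from the z-scored 465 nm trace.

Notes and limitations, all consequences of the recipe itself:

* **Median anchoring** makes the bleach line robust to calcium transients
  inside the flanks, unlike least squares; but when transients and a
  steep bleach coexist in a flank, the order statistics interact and the
  recovered pre-seizure mean can be biased by up to ~0.1 z-units.
* **The pre-seizure mean is bounded by 1.**  Because the pre-seizure mean
  is computed on the same 60-s window that supplies the z-scoring median
  and SD, and mean − median ≤ SD for any sample, pre-seizure activity
  lives on a bounded scale.  This is a structural property of
  median-baseline z-scoring, not of the data.
* **Motion cancellation is approximate.**  z-scored subtraction cancels a
  shared artifact exactly only when both channels' baseline SDs are
  dominated by that artifact.  Calcium signal in the 465 channel inflates
  its baseline SD, leaving a motion residual of order
  (σ_calcium/σ_motion)²/2.  The recovery tests therefore operate in the
  motion-dominant regime the method is designed for.
* **Degenerate isosbestic channel.**  A constant 405 baseline (possible in
  noise-free synthetic data) carries no artifact information; the
  session-level wrapper then skips the subtraction with a warning instead
  of failing the session.  Direct calls to `zscore_baseline` still raise.
* If the record is shorter than the 6-minute window it is clipped with a
  warning and the flanks shrink proportionally (10-s floor).

The during-seizure window is [induction, induction + max(ictal duration,
stimulation duration)), using the detected after-discharge duration and
falling back to the 10-s stimulation window when no after-discharge is
detected.

## Encoding model and contributions

A Gaussian identity-link GLM (least squares with intercept) predicts
per-recording seizure band power from the pre-seizure and during-seizure
activity means.  Contribution analysis, per bootstrap iteration: draw a
fresh uniform 70/30 train/validation split; resample the training rows
with replacement; fit the full and each drop-one GLM on the bootstrap
sample; score validation R² for each.  After `n_boot` iterations
(default 5000; cohort-level analyses in the tests use 1000):

* full-model performance = mean validation R² (may be negative; never
  clipped);
* contribution of predictor j = max(0, full − mean drop-j validation R²);
* relative contributions = contributions normalized to sum to 1, or all
  zero when no predictor helps.

Choices made where the procedure was underdetermined: the split is
redrawn every iteration (a flag fixes a single split instead), averaging
over split variance; validation rows are never part of the bootstrap
resample; validation R² on a constant validation response is defined
as 0; both raw declines and normalized shares are reported.  Contributions
are invariant to affine rescaling of any predictor (R² is scale-free),
which the tests assert.  With a fixed seed the whole procedure is
bit-reproducible.

## Seizure and behavior metrics

* **After-discharge detection** (a package surrogate for visual scoring —
  flagged as such in its output): the 4–14 Hz band-power envelope in 1-s
  epochs is thresholded at baseline mean + 3 SD (60-s pre-induction
  baseline; a numerical floor of 1e-6 × the peak envelope guards the
  noise-free case).  Supra-threshold epochs after stimulation offset are
  grouped, merging dropouts of ≤ 2 s; a recording is *provoked* when an
  event starts within 5 s of stimulation offset and lasts ≥ 2 s, and the
  whole event is the ictal duration.  One refinement over plain gap
  merging: an event ends at the last merged segment that itself lasts at
  least the minimum event length, so a single stray supra-threshold noise
  epoch near the tail cannot extend the measured duration (baseline-
  relative exceedances occur at any noise level; without this the
  duration-recovery correlation degrades on some cohorts).  All detection
  parameters are echoed into each result.
* **Seizure probability** = 100 × provoked / stimulations, exact; a
  half-up nearest-integer helper matches figure-legend style.
* **Fragmentation index** = maximal same-state bouts / total epochs of
  that state, over 5-s hypnogram epochs; in (0, 1], undefined (flagged,
  not 0) when the state never occurs.
* **State percentages** over a caller-supplied phase mask (light/dark
  bookkeeping is the caller's); **sucrose preference** = sucrose / total
  intake.

## Synthetic-data generator

The generator provides ground-truth-known sessions, not biophysics.  Two
latent z-scale activity levels drive each session: `latent_pre`
(pre-seizure HON activity) and `latent_during` (during-seizure surge).

**EEG**: white Gaussian baseline noise (SD 15 µV; a 1/f option exists but
is off by default so band-power expectations stay analytic), a sinusoidal
stimulation artifact (300 µV at the stimulation frequency, 10 s), and an
after-discharge starting at stimulation offset: a Tukey-tapered (α = 0.2)
oscillation whose instantaneous frequency sweeps from 12 to 6 Hz (the
upper-to-lower portion of the 4–14 Hz band).  Its amplitude is
100 µV × (0.5 + β_pre·latent_pre + β_during·latent_during) × g, with g a
lognormal session gain (σ = 0.06), and its duration is
12 s + 10 s × (β_pre·latent_pre + β_during·latent_during).  Linear
amplitude coupling makes band power quadratic in the latent, so
parameter-recovery expectations are closed-form.  The gain jitter models
session-to-session variability in seizure expression (electrode position,
network state); its σ was calibrated once so that a default 30-session
cohort yields a mean held-out encoding-model R² of ≈ 0.5, and then frozen.

**Photometry** (generated already demultiplexed; interleaved-acquisition
demodulation is out of scope): the 465 channel is offset 100 a.u. +
linear bleach (3 × 10⁻⁴ of the offset per second, ≈ 11% per session) +
calcium activity + shared motion + white sensor noise; the 405 channel
carries offset 80, its own bleach, the same motion, and noise.
Spontaneous calcium activity is a periodic train of rectangular bursts
(10-s period, amplitude 5 a.u.) whose duty cycle is
p = L²/(1 + L²) for L = latent_pre: for a two-level trace that is high a
fraction p < 1/2 of the time, the median sits at the floor and the
baseline mean in median/SD z-units is exactly √(p/(1−p)) = L.  That makes
latent_pre recoverable by the exact analysis chain (to ~2% with all
noise and artifact sources off, limited by duty-cycle quantization at
10 Hz).  Because of the mean − median ≤ SD bound above, recoverable
latents are bounded by 1; the cohort distribution is a normal(0.5, 0.2)
truncated to [0, 0.95], and duty is capped at 0.49 (pinned latents above
~1 saturate the photometry readout while still driving the EEG linearly).
During the seizure interval the burst train is replaced by a constant
surge scaled so the during-seizure mean recovers latent_during.  A
smoothed Gaussian "wiggle" (SD 0.3 a.u.) adds irregular fluctuations on
top of the deterministic burst train.

**Hypnograms** are first-order Markov chains over Wake/NREM/REM in 5-s
epochs; an ergodic chain's empirical state fractions match the stationary
eigenvector to 1% at 10⁵ epochs.

**Cohorts** draw latents i.i.d. per session; per-session seeds derive
from the master seed via `SeedSequence([master, index])`, so cohorts are
reproducible and sessions independent.  Every generator is a pure
function of (config, seed).

What the generator does **not** emulate: real HON calcium dynamics
(irregular event timing and amplitudes — the burst train is a stylization
chosen for exact recoverability), EMG, wake/sleep-state dependence of
seizure susceptibility, electrographic seizure morphology beyond a
band-limited oscillation, nonstationary or nonlinear bleaching, and
hemodynamic artifacts.  Passing recovery tests therefore demonstrates the
correctness of the analysis chain, not robustness to every property of
real recordings.

## Problem sizes and numerical conventions

Cohort-level analyses in the tests and the acceptance script use
30-session cohorts (the study's n = 30 recordings) with 1000 bootstrap
iterations, and 20 master seeds for across-seed claims; single-session
checks use the full 6-minute, 1 kHz sessions.  Ties and degenerate
inputs: validation R² with zero validation SST is 0; zero baseline SD
raises; an empty sleep state yields a flagged undefined result; the
after-discharge threshold has a 1e-6 relative floor.  All analysis
windows are half-open `[start, end)`; sample indices round half to even
via `int(round(...))` at 1 kHz, so window edges are exact at integer
seconds.
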