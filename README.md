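# periseizure

Peri-seizure analysis of simultaneous EEG and fiber-photometry recordings
in an acute mouse epilepsy model: seizure intensity as 4–14 Hz EEG band
power, isosbestic correction of hypothalamic hypocretin/orexin neuron
(HON) calcium photometry, and a bootstrap drop-one GLM that asks *which
epoch of neural activity — before or during the seizure — explains
seizure intensity*.

It is written for experimenters and analysts working with optogenetic
seizure-induction paradigms (EEG + dual-excitation photometry around a
known induction time), and for anyone who wants a tested, reusable
implementation of the analysis chain together with a synthetic-data
generator that makes every stage verifiable against known ground truth.

## What it computes

**Seizure intensity.** Raw EEG (1 kHz) is zero-phase low-pass filtered at
100 Hz and notch filtered at 50 Hz; a Welch PSD over non-overlapping 1-s
Hann epochs is integrated over the 4–14 Hz band of interest for the 30 s
after induction:

P = ∫₄¹⁴ Ŝ(f) df  (µV²),  Ŝ = mean over 1-s epochs of the tapered periodogram.

**HON activity.** Each photometry channel is detrended by the line through
the medians of the first/last 50 s of the 6-min peri-induction window,
z-scored by the median and SD of the 60 s before induction, and the
isosbestic (405 nm) z-trace is subtracted from the signal (465 nm)
z-trace.  Activity summaries are the mean corrected trace pre-seizure
(60 s before induction) and during the seizure.

**Relative contributions.** A Gaussian identity-link GLM predicts P from
(pre, during).  Over n_boot iterations: random 70/30 train/validation
split, bootstrap resample of the training rows, fit of the full and each
drop-one model, validation R² for each.  The contribution of predictor j
is max(0, mean R²_full − mean R²_without_j); relative contributions are
normalized to sum to 1.

**Ancillary metrics.** Threshold-based after-discharge detection and ictal
duration, seizure probability (% of stimulations provoking a seizure),
sleep fragmentation index (bouts / epochs per state, on 5-s hypnogram
epochs), state percentages, and the sucrose preference index.

**Synthetic sessions.** `periseizure.synthetic` generates coupled
EEG + photometry sessions in which a latent pre-seizure activity level
drives both the photometry baseline and the after-discharge
amplitude/duration, plus Markov-chain hypnograms — with full ground truth
for parameter-recovery testing.  See `docs/methods.md` for the model.

## Worked example

Run the full chain on a simulated 30-session cohort:

```yaml
# cfg.yaml
simulation:
  n_sessions: 30
  seed: 1
encoding:
  n_boot: 1000
output:
  dir: demo_out
```

```
$ periseizure run --config cfg.yaml
n=30  R2(validation)=0.496  relative contributions: pre=1.00 during=0.00
```

The report (`demo_out/report.json`) shows the encoding model explains
about half of the held-out variance in seizure power, and that dropping
the *pre-seizure* activity predictor accounts for essentially all of the
performance — the during-seizure predictor contributes nothing once
clipped at zero.  That is the qualitative dissociation the analysis is
designed to expose: in these simulated cohorts only the pre-seizure
latent drives the after-discharge, and the pipeline recovers exactly
that.  The report also carries per-session seizure outcomes, the cohort
Pearson correlations (pre vs power positive and significant; during vs
power inside the null band), seizure probability, and the full
configuration echo for provenance.

The same stages are available piecewise:

```
$ periseizure simulate --n 2 --seed 5 --out demo_cohort
wrote 2 sessions to demo_cohort
$ periseizure seizures --in demo_cohort
2/2 provoked (100.0%, 100% rounded); mean ictal duration 15.5 s
```

or from Python:

```python
import periseizure as ps

sess = ps.generate_session(ps.SimulationConfig(), seed=7)
power = ps.seizure_power(sess.eeg, induction_s=180.0)          # µV² in 4–14 Hz
corrected = ps.correct_recording(sess.photometry)               # z-units
outcome = ps.detect_afterdischarge(sess.eeg, 180.0, 10.0)       # provoked?, duration
activity = ps.epoch_activity(corrected, 180.0, outcome.duration_s)
```

The encoding model is a scikit-learn style estimator
(`BootstrapContributionGLM(n_boot, train_fraction, random_state).fit(X, y)`
with fitted attributes `r_squared_full_`, `contributions_`,
`relative_contributions_`), so it composes with sklearn tooling;
`contribution_analysis(...)` is the functional wrapper.

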