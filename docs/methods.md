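# Methods

## Problem and model

The decoder solves a two-class single-trial problem: given 1.2 s of
multichannel EEG locked to a speller's feedback onset, decide whether
the feedback was erroneous. The physiological signal of interest is the
interaction error potential: a positive deflection near 200 ms, a
dominant negativity near 250 ms and a second positivity near 320 ms
after feedback, with a fronto-central scalp maximum. The decoder is
deliberately subject-generic — trained on a pool of subjects and applied
unchanged to new ones — so every stage avoids subject-specific fitting
except ICA artifact cleaning, which is per recording.

## Synthetic data generator

The generator reproduces the *structure* the decoder relies on, not the
full physics of EEG:

- **Session plan.** Five sessions per subject: four of 12 five-letter
  words and one of 20, one feedback period per letter (60/60/60/60/100),
  onsets every 4.5 s after a 5 s lead-in. Each word is assigned a
  spelling condition (long/slow or short/fast flash sequence) with
  probability 0.5; error labels are Bernoulli with per-condition rates.
- **ErrP template.** Three Gaussian-windowed lobes at 200/250/320 ms
  with amplitudes +2/−5/+3 µV (before gain) and 25 ms SD, zero before
  onset, amplitude linear in the subject's `errp_gain`, latency jittered
  per trial (SD 10 ms). Because the two positive lobes are asymmetric
  the template's trough sits at 251.5 ms rather than exactly 250 ms —
  within one sample period at 200 Hz.
- **Topography.** Weight 1.0 at Cz/FCz decaying by 0.6 per grid step of
  10–20 distance. This is a caricature of volume conduction, adequate
  for testing channel selection, not for source analysis.
- **Background.** Independent per-channel 1/f-amplitude noise (RMS
  3 µV by default), a 10 Hz alpha rhythm (1.5 µV) on parieto-occipital
  channels, and biphasic 300 ms blinks (Poisson 0.2/s, ~80 µV on EOG)
  leaking 0.3 into Fp1/Fp2 and 0.15 into the AF row.

Default parameter values and what they mean:

| parameter | default | rationale |
|---|---|---|
| `errp_gain` | 1.0 | template at its nominal µV amplitudes |
| `noise_rms` | 3 µV | a clean, high-SNR desk-scale regime in the 0.1–10 Hz band, so decoder recovery is expected rather than marginal |
| `error_rate_fast` / `error_rate_slow` | 0.35 / 0.20 | consistent with a corpus-wide error fraction near 0.29; the split between conditions is a convention |
| `latency_jitter_sd` | 10 ms | moderate trial-to-trial latency variability |
| blink model | 0.2/s, 80 µV | large enough that ICA cleanup is measurable, small enough not to swamp the scalp |

What passing tests on this data do **not** show: robustness to real
inter-subject variability, non-stationarity, correlated noise fields,
muscle artifacts, or realistic single-trial SNR. On real recordings the
same pipeline would be expected to score far lower (AUC ~0.7 rather
than ~0.95).

Determinism: every public generator call takes a seed; per-subject and
per-session seeds are derived through `numpy.random.SeedSequence`, so a
corpus is bit-reproducible given its master seed.

## Preprocessing

- **Band-pass** 0.1–10 Hz elliptic, design order 4 (8 poles as a
  band-pass), 1 dB ripple, 50 dB stopband, applied causally
  (forward-only) so the offline and streaming paths share one code path;
  the group delay this introduces is accepted. Note an elliptic design
  has an equiripple stopband: DC is attenuated by exactly the 50 dB
  floor, not nulled.
- **ICA ocular cleaning** (FastICA, full rank by default) runs on ≥60 s
  of band-passed scalp data; components with |Pearson r| > 0.7 against
  the recorded EOG lead are subtracted via back-projection, which leaves
  the retained subspace numerically untouched — a blink-free recording
  passes through unchanged. Non-convergence is recorded in the report
  rather than fatal. The end-to-end transfer pipeline leaves this stage
  off by default (`DecoderConfig.eog_removal`): blink leakage is
  anterior while the decoding weight is fronto-central, and the stage is
  verified by its own tests; the CLI `preprocess` command enables it for
  data that needs it.
- **Savitzky–Golay smoothing**: cubic, 31-sample window, implemented as
  the closed-form convolution kernel (coefficients sum to 1; reproduces
  all polynomials of degree ≤ 3 exactly on interior samples). Edges are
  mirror-padded. In the per-trial path each 240-sample block is
  prepended with the trailing 100 ms (20 samples) of the previously
  processed block before smoothing — the same rule the streaming decoder
  applies — with mirror padding standing in on the first block.

## Features

Epoch [−200, +1000) ms = 40 + 200 samples at 200 Hz. Baseline
correction subtracts the pre-onset mean per channel (exactly zero mean
afterwards by construction). The 200 post-onset samples are averaged in
8 contiguous bins of 25 samples; bin means rather than decimation
because the printed feature dimensionality (8 per electrode, 448 for 56
electrodes) is the binding constraint and averaging is the
noise-robust choice. Nine experiment features complete the vector:
grand mean and population variance of the baseline-corrected epoch,
plus session number, feedback number, alphabet position, word number,
total feedback, total word and sequence type (long = 1).

The grand mean/variance are computed over the channels *in use*: the
feature table stores per-trial per-channel first and second moments so
that any electrode subset yields exactly the moments the streaming
decoder (which only acquires selected channels) would compute. All
features are z-scored with training-set statistics before
classification; the standardizer is stored in the model.

## Channel selection

Single greedy pass over electrodes in montage order. For each
electrode, the 10-fold cross-validated AUC of the ensemble decoder
without it is compared with the current reference; removal is accepted
(and the reference updated) iff the AUC does not decrease — ties favour
the smaller model. Experiment features always stay. By construction
the final AUC cannot fall below the initial full-montage AUC. The
selection objective is the deployed decoder itself, not a cheaper
proxy; with 56 electrodes this costs 57 cross-validation runs.

## Ensemble decoder

Resamples: the M = k = 10 training splits of a stratified k-fold
partition (each of size n(k−1)/k, without replacement). A
with-replacement bootstrap variant is available behind a flag.

Learners, each fitted on every resample (L×M = 40 estimators):

- **LDA** — closed-form pooled-covariance Gaussian discriminant with a
  1e-6 ridge for rank safety.
- **QDA** — per-class covariances shrunk as
  Σ_c ← (1−γ)Σ_c + γ·(tr Σ_c/d)·I with γ = 0.07. LDA/QDA are
  implemented in-package because this exact shrinkage form is part of
  the decoder's definition; a Cholesky failure escalates a logged
  ridge jitter rather than aborting.
- **Logistic L1 / L2** — scikit-learn, penalty weight λ = 0.15
  (C = 1/λ), liblinear/lbfgs. liblinear penalizes the intercept, which
  is mitigated with `intercept_scaling = 100`; λ is read as the penalty
  weight (not its inverse).

Class priors come from resample frequencies; no imbalance correction is
applied. The ensemble posterior is the arithmetic mean of all L×M
error posteriors (the only reading of "divide by LM" that yields a
proper probability); the label is Error iff the posterior ≥ 0.5
(boundary inclusive).

## Streaming decoder

The pseudo-online path keeps: the causal filter state, a 400-sample
ring buffer of filtered data for the selected channels, the pending
marker positions, and the 20-sample carry-over from the last processed
block — state independent of stream length. A prediction is emitted as
soon as t+1000 ms of data has arrived. A marker inside the first
200 ms is served by mirror padding and logged. Because batch
featurization uses the identical block pipeline and the chunked filter
carries exact state, streaming and batch posteriors agree to rounding
(tested at 1e-9, observed exactly equal).

Computation time is measured around the feature-extraction +
classification step only and reported in microseconds; absolute values
are hardware-specific and never treated as reproducible.

## Evaluation

Error is the positive class. AUC is pairwise concordance with ties
counted 0.5 (computed via mid-ranks; equal to the ROC trapezoid). F1
is 0 by convention when precision + recall = 0; with one class present
AUC is reported as undefined while the other metrics are returned.
Rank tables use mid-ranks on ties; the Friedman statistic is evaluated
directly from average ranks, and the critical value is a user-supplied
constant. Recomputing the statistic from a *printed* (rounded)
average-rank column reproduces published values to ~0.1% — the rounding
of the rank column, not the formula, limits the agreement.

## Numerical and design notes

- Chance-level validation uses a generator profile with **equal**
  fast/slow error rates: with unequal rates the sequence-type feature
  legitimately predicts the label even without any evoked response, so
  equal rates are the correct independence construction for a null.
- Desk-scale problem sizes: property tests run on 16–20-trial sessions;
  the transfer-recovery suite trains on 4 subjects (1,360 trials) and
  tests on 2 (680 trials), with a 680-trial null corpus — sizes chosen
  so the full suite completes in a couple of minutes while keeping all
  structural constants (sessions, words, counters) at their real values.
- `train_decoder` clamps the fold count to the minority-class count on
  very small fixtures (logged); defaults remain k = M = 10.
- Reader code validates and rejects malformed files (duplicate or
  missing columns, non-uniform time base, marker values outside {0,1},
  posteriors outside [0,1]) rather than repairing them.

## Known limitations

- The generator's spatial model is a distance decay, not a head model;
  channel-selection results on synthetic data say nothing about which
  *real* electrodes matter.
- Only 200 Hz recordings are supported; no EDF/BDF/FIF ingestion.
- No post-hoc tests beyond the Friedman statistic, and no confidence
  intervals on AUC.
- The competitor learners that appear in published rank tables (SVM,
  bagging, boosting) are not implemented; the evaluation module ranks
  externally supplied metric tables instead.
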