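# Methods

This note records the model and procedure the package implements, the
defaults that matter, the design choices that were genuinely open, and what
the synthetic experiments do and do not demonstrate.

## Signal model and pipeline assumptions

EEG trials are treated as channels × samples matrices in microvolts at a
fixed sampling rate (canonically 14 channels, 1,280 samples, 128 Hz — a
10-second trial). The pipeline assumes that class-discriminative content
lies *outside* 4–15 Hz while theta/alpha (4–15 Hz) carries ocular artifact
and subject-specific confound rather than class signal: that assumption is
what makes a band-*reject* filter information-preserving. Units are taken as
delivered; no rescaling is applied, since every stage up to normalization is
scale-covariant and Phase 6 removes scale entirely.

### Phase 1 — ICA artifact removal

The "2.5σ / 99.99% variance" rejection rule needed two interpretation
decisions, both exposed as configuration:

- *Variance retention* is implemented as PCA rank selection before
  unmixing: the smallest rank whose cumulative explained variance reaches
  `variance_retained` (default 0.9999). That is the only place a
  variance-retention knob exists naturally in an ICA pipeline.
- *The 2.5σ referent* is the across-component distribution of a
  per-component artifact statistic: a component is zeroed when its score
  exceeds mean + 2.5σ of all component scores in the same fit. The
  statistic is `max_of_both` by default — the larger of the peak-amplitude
  z and the excess-kurtosis z — matching standard automatic IC-rejection
  practice (blinks are high-amplitude, EMG bursts heavy-tailed).

ICA is fit per subject by default (`fit_scope="per_subject"`, all of a
subject's trials concatenated), which stabilises the unmixing estimate and
is label-blind, so it may run before any train/test split without label
leakage. A caveat is documented rather than hidden: fitting on data that
includes eventual test trials is a (label-free) form of transductive
preprocessing; `per_recording` scope is available where that matters. Fits
with fewer than 10·n_channels² samples are skipped with a warning and an
identity transform rather than returning an unstable unmixing. The solver
behind the surface is scikit-learn's FastICA; the rank selection, scoring,
rejection, and reconstruction logic are this package's.

### Phases 2–4 — zero-phase band-reject

The mask over the non-negative frequency grid is 1 below 2 Hz, a raised
cosine from 1 → 0 on [2, 4] Hz, 0 through [4, 15] Hz, a raised cosine
0 → 1 on [15, 17] Hz, and 1 above. Transition ramps are placed *outside*
the nominal stopband so the whole 4–15 Hz interval sits at exactly zero
gain. A real non-negative mask applied once is already zero-phase, so the
default is a single application; a `squared_gain` option reproduces the
literal forward–backward magnitude (the square of the mask) for anyone who
reads "forward–backward" as two passes. Both behaviours are tested; they
differ only in the ramp steepness.

DC and Nyquist handling follow the real-FFT convention (`rfft`/`irfft` with
explicit output length), which keeps odd-length signals exact and the round
trip below 1e-10.

The `td_bandreject` comparison mode is a zero-phase forward–backward
Butterworth band-stop (default order 4) over the same 4–15 Hz band — the
conventional temporal filter the frequency-domain path is compared against.

### Phase 5 — segmentation

Windows start at 0, stride, 2·stride, … while start + ws ≤ n_samples;
trailing samples that do not fill a window are dropped (the canonical
sliding-window convention; exact for every configuration used here, since
(1280 − 32)/8 and (1280 − 8)/8 are integers). Scheme A is 32/8
(overlapping, 250 ms windows), Scheme B 8/8 (non-overlapping, 62.5 ms).
Windows never cross recording boundaries, and each window records its
source recording and start sample so leakage audits can reason about raw
sample spans.

### Phase 6 — normalization

Per-channel mean and *population* standard deviation are pooled over all
training windows and timepoints; the sd is clamped at ε = 1e-8 to guard
constant channels. Statistics are never refit on the set being transformed,
and a double-normalization guard raises rather than silently re-scaling.

## Architectures and training

The five structural templates (conv block present or absent; 1–3 recurrent
layers, unidirectional or bidirectional; dropout placements 0.20 / 0.50–0.20
/ 0.50–0.50 / 0.10–0.30–0.10–0.10; one or two dense layers) are fixed.
Layer *widths* are not part of the templates and are set by profile:
`full` uses 64 conv filters (kernel 3, pool 2), LSTM units
(128,), (128, 64), or (128, 64, 32) by depth, and dense 128/64;
`tiny` (the test and experiment default) uses 8 filters and 16-unit layers.
Widths are this package's choices — reported parameter totals for these
models are internally inconsistent (a conv-free variant listing
batch-normalization-sized non-trainable counts), so no attempt is made to
force them; parameter accounting is instead verified against closed-form
layer formulas: conv (k·in+1)·f, LSTM 4·((in+u)·u+u) (doubled when
bidirectional), dense (in+1)·out, batch normalization 2f trainable + 2f
running moments. Model size in MB is total parameters × 4 bytes / 2²⁰.

The layer stack, backpropagation, and Adam optimiser are implemented in
NumPy inside `imspeech.models`. This keeps the package light, makes
parameter accounting exact, and gives bit-identical histories for identical
seeds on CPU. The cost is speed: the `full` profile trains slowly
at realistic dataset sizes, which is why the experiments here use the tiny
profile (see "Problem sizes" below).

Training details that the headline description leaves open, decided here:
the validation carve-out for early stopping is a stratified 10% of the
training partition, seeded; the weights of the best-validation epoch are
restored when training stops; the learning-rate plateau uses min_delta
1e-4, early stopping uses strict improvement. One-hot targets, no label
smoothing, no class weighting (synthetic classes are balanced by
construction). Fine-tuning clones the pretrained model (the input is never
mutated), resets lr to 0.001, forces batch 128, and applies the same
stopping criteria.

## Evaluation

- *Strategy 1* stratifies at the window level (whether the split operates
  on windows or recordings was unstated; window-level is assumed and
  documented). It tolerates temporal leakage by design and is reported as
  the optimistic upper-bound protocol.
- *Strategy 2* defaults to `group_key="window"` — stratified k-fold over
  non-overlapping windows ("sample-level grouping"). Because that reading
  admits alternatives, recording- and subject-level grouping are also
  implemented (via stratified group k-fold). In strict mode the
  generator refuses overlapping Scheme A windows with a temporal-leakage
  error rather than producing an audit failure later.
- *Strategy 3* builds one fold per subject; the held-out subject's windows
  are split stratified-by-class into 20% calibration / 80% test. The audit
  asserts that test and calibration windows share exactly one subject and
  that the subject is absent from training.

Metrics are computed from the confusion matrix by direct formula; tests
cross-check them against an independent per-sample brute-force oracle and
against scikit-learn. Two identities hold exactly and are asserted:
support-weighted mean recall ≡ accuracy, and balanced accuracy ≡ macro
recall. Zero-support classes are excluded from macro averages with a
warning (the real protocol never encounters this).

Confidence margins use the Student-t multiplier with df = n − 1 — the
convention validated by recovering t(4) = 4.12 from the reported 30-class
summaries (99.38 ± 0.08 vs 94.14 ± 3.53, five seeds). Both Cohen's d
conventions are implemented explicitly because the two reported effect sizes
are reproducible only with d = t·√(2/n) for the five-seed comparison and
d = t/√n for the 20-subject paired comparison. A reported
coefficient-of-variation table (13.05% where sd/mean gives 12.5%) could not
be reconciled with any CV definition tried; CV is computed as sd/mean here
and the discrepancy is noted, not patched.

## Synthetic data: what it emulates, what it does not

Each class owns a deterministic template — a carrier frequency evenly
spaced inside 18–40 Hz (outside the stopband) and a fixed unit
channel-loading vector — amplitude-modulated per trial, mixed with 1/f
(pink) plus white background noise at a configurable SNR, scaled to a
physiological ~10 µV RMS, then passed through per-subject log-normal
channel gains and small DC offsets. Optional artifacts: frontal Gaussian
blink pulses (0.5–3 Hz energy), ≥25 Hz EMG bursts on temporal channels,
sustained 50 Hz line noise, and a *subject-linked* 8–12 Hz alpha confound
whose frequency and amplitude are fixed per subject and class-blind.

Three named scenarios freeze the desk-scale study conditions:

- `scenario_separable` — 2 subjects × 6 classes × 3 trials of 256-sample
  recordings at +15 dB SNR, no artifacts: the "can the pipeline learn at
  all" benchmark (≥ 90% random-split accuracy expected).
- `scenario_alpha_confound` — 3 subjects × 3 classes × 4 trials at +3 dB
  with a 25 µV subject-linked alpha oscillation, well above the class-signal
  RMS so the confound dominates cross-subject variance: full-band inputs
  transfer poorly across subjects while 4–15 Hz rejection removes the
  confound entirely (FD-F ≥ full-band under LOSO).
- `scenario_subject_shift` — 3 subjects × 3 classes × 4 trials with strong
  per-subject gains (log-normal σ = 0.6): the calibration use case
  (fine-tuned LOSO strictly beats uncalibrated LOSO).

The generator is a statistical emulation, not a biophysical one: no head
model, no volume conduction, no dipole sources, no non-stationarity beyond
the event structure, and class information is narrow-band by construction.
Passing tests therefore demonstrate that the pipeline's *mechanisms* work —
artifact components are separable and removed, the stopband deletes what it
should and nothing else, leakage-aware splits behave as specified,
calibration recovers subject shift — not that any particular accuracy will
be attained on real recordings, where class information is broadband, weak,
and entangled with exactly the bands this pipeline discards.

## Problem sizes and numerical choices

End-to-end experiments run on 256-sample recordings (2-second trials), the
tiny model profile, and a 25-epoch / patience-8 training budget; these are
the package's declared desk-scale conditions, chosen so the whole suite and
the acceptance script each complete in well under a minute of training per
experiment on one CPU while leaving every mechanism intact. The full
1,280-sample geometry is exercised by the windowing, filtering, and IO
tests; nothing in the implementation is specialised to the short trials.

Tie-breaks and degenerate inputs: max-pooling takes the first maximum;
constant channels raise in ICA (rank-deficiency) and clamp in
normalization; empty manifests, empty calibration sets, single-class
training sets, inverted stopbands, ramps crossing 0 Hz or Nyquist, and
windows longer than recordings all raise named errors rather than
proceeding.

## Known limitations

- No real-dataset loader beyond generic CSV/EDF: results on the actual
  Kaggle-hosted benchmark require downloading it and training the
  `full` profile, which this CPU implementation makes slow.
- The NumPy trainer is single-threaded per fold and offers no GPU path.
- EDF support is read-only; the writer in the test fixtures is a minimal
  synthetic encoder, not an exporter.
- ICA rejection thresholds are distribution-relative; on data with many
  true artifact components the across-component mean shifts and the 2.5σ
  rule becomes conservative.
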