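# Methods

`ictalnet` implements a cross-patient epileptic-seizure detector for
multichannel scalp EEG in the CHB-MIT convention (23 leads, 256 Hz, 16-bit
EDF), together with everything needed to exercise it without the corpus:
a synthetic-EEG generator, the labeling and feature pipeline, the network,
training, and the evaluation protocol.  This note records the model, the
choices made where the published description is silent, and what the
synthetic world does and does not establish.

## Problem and labeling conventions

Windows of EEG are classified as *ictal* (during a seizure) or *interictal*
(between seizures).  The labeling rules follow the common CHB-MIT protocol:

* **Seizure merging** — consecutive seizures separated by less than 30
  minutes (`merge_gap_s = 1800`) count as one event; merging is transitive.
* **Interictal buffer** — interictal time must lie at least 4 hours
  (`buffer_s = 14400`) from any seizure.  Time inside the buffer but outside
  a seizure belongs to neither class and produces no windows.
* **Patient inclusion** — subjects with more than 10 seizure onsets inside
  any 24-hour window are excluded.  The sliding maximum is evaluated with
  windows anchored at each onset, which attains the supremum.  The count
  uses merged events; whether the original protocol counted raw or merged
  events is not documented, and merged counting matches the published
  per-patient seizure tallies more closely.
* **Windowing** — each labeled segment is tiled from its start into
  consecutive, non-overlapping 30-second windows; a trailing remainder is
  dropped.  Windows never overlap, which the tests verify pairwise.

Both durations above are parameters: at synthetic-fixture scale (minutes of
record rather than days) the tests and pipeline default to a 120 s merge gap
and a 60 s buffer — the same rules, scaled to the length of the records.

## Features

Each 30 s window is converted per channel to a magnitude spectrogram with a
Gaussian-window short-time Fourier transform:

    X[c, k, m] = | sum_n  x[c, m*hop + n] * w[n] * exp(-2*pi*i*k*n/L) |

The published description names the Gaussian window but fixes no
parameters; the defaults here are L = 256 samples (1 s, giving 1 Hz
resolution), sigma = L/8 = 32 samples, hop = 128 (50 % overlap), one-sided
spectrum, no padding (trailing partial frame dropped), and log(1+|.|)
compression.  A 30 s, 256 Hz window therefore yields a (23, 129, 59)
tensor ordered (channel, frequency, time).  An optional `freq_crop_hz`
restricts the feature to 0-40 Hz, the band where ictal energy concentrates;
the training examples and pipeline use it to cut compute by ~3x.

Spectrograms are z-normalised per channel with training-set statistics
before entering the network.  An optional ICA denoising stage (off by
default, since no operational details are published) decomposes each window
into as many independent components as channels and zeroes components whose
excess kurtosis exceeds 5 in magnitude — the signature of spike artifacts;
non-convergent decompositions pass through unchanged with a warning.

## Class balancing and the split

Seizure windows are rare, so the minority class is oversampled with
replacement up to the majority count and a seeded random dropout trims any
excess so counts end exactly equal; every balanced sample is a copy of a
real window (no interpolation).  The split is 80/20, seeded and stratified
by class.  **Order matters**: balancing before splitting would leak
duplicated minority windows into the test set, so the split happens first
and only the training portion is balanced.  This deliberately deviates from
the published flow diagram, which draws balancing before the split; the
leakage-free order is the defensible one and the evaluation otherwise
inflates.

## The network

Input is the (D=23, H=frequency, W=time) spectrogram, treated as an
H x W image with D feature channels.

* **pre-CNN**: three 3x3 convolutions with 16 output maps each, strides
  (1, 1, 2), each followed by GELU, batch normalisation and dropout.  The
  published text reads "the total number of convolutional kernels is 16",
  interpreted as 16 maps per layer (16 split across three layers is not an
  integer).  The stated order conv -> GELU -> BN is implemented literally,
  with a config switch for the conventional conv -> BN -> GELU.
* **Two transformer stages**, alternating with convolution: each stage
  opens with a 3x3 stride-2 convolution to the stage dimension (32, then
  64) plus layer normalisation, followed by a block of
  * **local perception unit** `X' = Conv3x3(X) + X`, the residual
    convolution that replaces positional encoding and preserves translation
    invariance;
  * **light multi-head self-attention**: queries from all L = H*W tokens;
    keys and values from the L' tokens of a stride-2 depthwise-separable
    3x3 reduction of the map, so the score matrix is L x L' ~ L^2/4 —
    the "light" in the name.  8 heads; scores scaled by 1/sqrt(d_k).  The
    published formula prints QK^T/d_k without the radical; this is read as
    a typographical loss (the original transformer scaling is cited), and a
    `scale_by_sqrt=False` switch restores the literal form.  Pre-LN
    residual arrangement: `X'' = X' + LMHSA(LN(X'))`.
  * **residual feed-forward network**: 1x1 conv expanding D -> 4D, GELU,
    depthwise 3x3, GELU, 1x1 conv back to D, plus the skip.  Expansion
    ratio and activation are unstated; 4 and GELU follow transformer
    convention.
* **Fusion head**: global average pooling, a fully connected layer to two
  logits, log-softmax.  Classification thresholds the ictal probability at
  0.5; a tie resolves to ictal (the clinically conservative direction).

All convolutions use "same" padding with ceil semantics for strides, so the
spatial chain is 129x59 -> 65x30 -> 33x15 -> 17x8.  Weights are
truncated-normal (std 0.02), biases zero, all seeded.

### Numerical substrate

No deep-learning framework is assumed: the network runs on a small
reverse-mode autodiff engine (`ictalnet.autodiff`) over numpy arrays, with
grouped 2-D convolution implemented by im2col + BLAS matmul.  Every
primitive and the composed layers are gradient-checked against central
differences.  The engine preserves dtype; training uses float32 (about 2x
faster on one core), all oracle comparisons run in float64.

### Training

Adam (beta1 0.9, beta2 0.999, eps 1e-8, no weight decay, no schedule — none
are published), learning rate 0.01, batch size 32, 50 epochs, binary
cross-entropy on the log-softmax pair (identical to two-class NLL); focal
(gamma 2) and hinge losses are available for comparison.  Mini-batches are
reshuffled each epoch from a seeded generator; training aborts with a
diagnostic on non-finite loss.

**Batch-norm recalibration.** At lr 0.01 the weights move quickly, so the
exponential running estimates BN keeps for inference lag the final weights
badly (measured ~2x variance mismatch after a short run), which wrecks
eval-mode calibration even when the ranking (AUC) is perfect.  After the
last epoch, one pass over the training set with frozen weights, dropout
disabled and cumulative averaging replaces the running statistics with
full-data statistics under the final weights — the same remedy
stochastic-weight-averaging implementations use.  This is a calibration
step, not extra training.

### Evaluation

One model is trained on the pooled training windows of all included
patients (the cross-patient protocol); metrics are computed per patient on
that patient's held-out windows and macro-averaged.  Accuracy, sensitivity,
specificity, precision and F1 come from the 2x2 confusion at the threshold;
AUC integrates the ROC curve by the trapezoid rule over thresholds swept at
midpoints between consecutive unique scores plus infinite anchors.  The
trapezoid area equals the Mann-Whitney pairwise-concordance statistic on
tie-free scores, and the tests assert this to 1e-10.  A metric with a zero
denominator is reported as missing (None), never as 0, and is excluded from
the macro average.  AUC is computed per window; per-event aggregation is
not described in the source protocol and is not implemented.

## Synthetic world

The generator emulates exactly what the pipeline expects from the corpus:
23-channel 256 Hz records written as 16-bit EDF (physical range +-500 uV,
so one quantization step is ~0.015 uV) plus a summary text in the CHB-MIT
dialect.  Background is Gaussian noise shaped to 1/f^beta (beta = 1) at
30 uV RMS — the simplest spectrally realistic surrogate for ongoing EEG.
Each seizure is a burst of 2-3 random-phase sinusoids drawn from 3-7 Hz,
Hann-enveloped, at `ictal_gain = 3` times the background RMS, shared across
channels with per-channel gains in [0.5, 1.5] (seizures in scalp EEG are
broadly visible across leads).  Defaults: 4 patients, 1800 s records, 2
seizures of 60-120 s at least 300 s apart (>= 2x the fixture-scale
interictal buffer, so interictal windows always exist).  Seizure endpoints
are rounded to whole seconds, matching the annotation convention and making
summary round-trips exact.  Same seed, same patient index: bit-identical
output.

What the synthetic world does **not** contain: artifacts (blinks, EMG,
electrode pops), non-stationary background, inter-patient morphology
differences beyond the random burst parameters, or any ambiguity between
classes.  A green end-to-end test therefore establishes that the
implementation is correct and that the architecture can learn a strongly
separable time-frequency signature through the full pipeline — it says
nothing about clinical performance, and the published corpus-scale numbers
(ACC 92.89 %, SEN 96.17 %, SPE 92.99 %, F1 94.41 %, AUC 96.77 %) are not
reproducible without the corpus and are not claimed by any test here.

## Degenerate inputs and edge rules

* Intervals with end <= start, overlapping annotations, declared/parsed
  seizure-count mismatches, truncated EDF data regions and zero-channel
  files are rejected with explicit errors.
* A configuration whose seizures cannot fit in the record raises a sizing
  error rather than overlapping bursts.
* Segments shorter than 30 s yield no windows; a class with zero members
  cannot be balanced and says so.
* Undefined metrics are None; AUC with a single class present raises.
* Patients with an empty test set are skipped with a warning during
  evaluation, not silently averaged.

## Reproducibility

Every stochastic component (generator, split, dropout, initialisation,
batch shuffling) draws from an explicit seed; the pipeline derives stage
seeds from one global seed by fixed offsets and stamps every artifact with
a hash of the scientific configuration (paths excluded).  Running the
pipeline twice with the same config and seed produces byte-identical
evaluation reports, which the acceptance tests assert.
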