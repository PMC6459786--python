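# Methods

## Problem and scope

Intracranial EEG (iEEG) recorded for drug-resistant epilepsy evaluation
is contaminated by muscle and movement artifacts, machine transients,
and power-line interference, while also containing pathological activity
(interictal spikes carrying high-frequency oscillations, HFOs) that an
artifact detector must *not* remove. `ieegart` implements a supervised
pipeline that classifies 3-s single-channel segments into physiological
iEEG, pathological iEEG, power-line noise (50/60 Hz), and non-cerebral
artifact, and slides the classifier over continuous recordings to build
channels × seconds Artifact / Pathology Probability Matrices (APM /
PPM).

Clinical gold-standard data is available only on request from the
originating institutions, so the package ships a synthetic segment
generator that emulates the four classes; every quantitative claim the
test suite makes about classifier quality refers to this synthetic
study set, not to clinical data.

## Feature construction

Each segment (15,000 samples at 5 kHz) becomes a 5 × 15000 input
matrix:

| row | content |
|-----|---------|
| 0 | raw trace low-passed at 900 Hz |
| 1 | envelogram 20–100 Hz (beta, low/high gamma) |
| 2 | envelogram 80–250 Hz (ripples) |
| 3 | envelogram 200–600 Hz (fast ripples) |
| 4 | envelogram 500–900 Hz (very fast ripples, muscle) |

An *envelogram* is the squared magnitude of the analytic signal
(signal + i·Hilbert transform) of the band-passed trace — an
instantaneous band-power series. The magnitude of the Hilbert transform
alone oscillates at the carrier frequency and is not an envelope, hence
the analytic-signal reading. All filters are 3rd-order Butterworth
applied forward–backward (`sosfiltfilt`): zero net phase, effectively
6th-order magnitude. Edge transients are stabilized by the default
odd-reflection padding; the interior of a 3-s segment is unaffected by
the choice. Each row is z-scored with the population standard
deviation (a constant row maps to all zeros), which removes absolute
amplitude units from the problem.

Acquisition-rate data is brought to the 5 kHz pipeline rate by a
Bartlett–Hann-windowed FIR low-pass with 1 kHz cutoff followed by
polyphase resampling (rational ratios supported). The tap count scales
with the working rate (257 taps per 5 kHz) so the transition band stays
a few hundred Hz wide; at 32 kHz → 5 kHz a 2.4 kHz tone is attenuated
by ≈ 74 dB and passband amplitude is preserved to < 1%.

## Classifier

A 1-D convolutional network over time, with the five feature rows as
input channels: stacked blocks of [convolution → batch normalization →
ReLU → non-overlapping max pooling], then dropout and two fully
connected layers ending in a softmax. Cross-entropy plus an L2 weight
penalty is minimized with Adam.

Defaults: the first convolution uses stride 5 (a 1 ms output grid at
5 kHz — the high-frequency content of the raw row is already
summarized by the envelogram rows, so full-rate conv outputs are
redundant), followed by four blocks with 8/16/32/32 filters, kernel
length 9 and pool length 4 (15000 → 3000 → 750 → 187 → 46 → 11 time
steps), a 64-unit hidden dense layer, dropout 0.5, L2 1e-4 — about
38,000 parameters. These sizes are the package's own choice: they
preserve the block pattern while keeping a full training run practical
on a single CPU core; every value is exposed in `ModelConfig` and
stored in checkpoints. Convolution weights use He-normal initialization, batch
norm uses eps 1e-5 and momentum 0.1 for running statistics, and
evaluation mode (running statistics, no dropout) is fully
deterministic.

Forward and backward passes are implemented in numpy (convolutions as
per-tap BLAS matrix products); the test suite verifies every layer's
analytic gradient against central finite differences in float64.
Max-pool gradients are routed to all maximal samples of a pool window;
for continuous inputs ties have probability zero, so this coincides
with argmax routing.

## Training and early stopping

Training minimizes loss on the training split and evaluates validation
loss after every epoch (forward-only: weights and running statistics
are not updated by validation). It stops when validation loss has not
improved by at least `early_stop_min_delta` for `early_stop_patience`
consecutive epochs, or at `max_epochs` (default 25), and restores the
weights of the best validation epoch — returning a model from after
the decline would waste the stopping signal. Defaults: Adam at 1e-3,
batch 32, patience 1, min-delta 0. Splits are stratified per class
with floor rounding, remainder to train. No class reweighting is
applied by default.

## Transfer learning

To adapt a trained model to a new site or class set (e.g. adding a
60 Hz line-noise class), the softmax head is replaced by a fresh
normal-initialized layer (mean 0, std 0.01) sized to the new class
set, and all transferred layers are retrained at
`transfer_lr_fraction` (default 10%) of the head's learning rate,
implemented as per-layer learning-rate scaling inside Adam. The std
0.01 head initialization is a conventional small-scale choice; only
"normal with mean zero" is constrained by the method.

## Sliding-window detection

For each channel independently, 3-s windows advance in 1-s steps (2-s
overlap) so every interior second is the *center* of some window; the
window's class probabilities are assigned to its center second. The
first and last seconds have no centered window and replicate the
nearest centered column so the matrix spans all floor(duration)
seconds; a trailing fraction of a second is dropped. Binarization is
strict (`p > 0.95` by default: "higher than 95%"), and events are
maximal per-channel runs of supra-threshold seconds, with runs shorter
than `min_duration_s` discarded — run-length filtering is the only
morphological operation implemented; further image-morphology
post-processing is out of scope.

## Synthetic data generator

The generator's defaults define the study conditions:

* **Background** (all classes): 1/f-amplitude ("pink") noise, flat
  below 1 Hz, normalized to std = `background_amplitude` (1.0), plus
  1–3 amplitude-modulated 8–30 Hz oscillations at 0.15–0.5 of the
  background amplitude. Band power above 500 Hz is ~3 orders of
  magnitude below the 1–100 Hz power.
* **Pathological**: 1–5 biphasic sharp transients (difference of two
  offset Gaussians, 50–100 ms, 5–10× background std, random polarity),
  each with a Hann-windowed 100–400 Hz burst (40–100 ms, 1.5–3× std)
  centered on the spike peak — a spike with an HFO riding on it.
* **Line noise**: a sinusoid at 50 or 60 Hz with weak 3rd (15%) and
  5th (5%) harmonics, amplitude `artifact_snr` (4) × background std.
* **Artifact**: one of three variants — a 100–1800 Hz band-passed
  noise burst of 0.5–2 s (muscle, 60% of draws), a sustained baseline
  step of 12–20× std (movement, 20%), or a flat-topped clipped
  transient of 10–16× std (machine, 20%).

Amplitudes are in arbitrary units because z-scoring removes scale; the
values above were chosen to give clearly separable but not degenerate
classes, which a band-power logistic-regression oracle confirms
(> 0.8 accuracy, independent of the CNN). All draws flow from one
explicit seed per call through spawned per-segment generators.

What the generator does **not** emulate: spatial correlation between
channels, seizure (ictal) patterns, scalp-reference artifact
propagation, electrode-specific noise floors, or the long-tailed
amplitude statistics of real iEEG. Passing the synthetic benchmarks
therefore demonstrates that the pipeline is implemented correctly and
can learn the intended class structure — not that the published
clinical performance figures transfer to any particular recording.

## Benchmark problem sizes

The standard synthetic study run (`ieegart.validation`) uses 300
training, 100 validation and 100 test segments per class for the
4-class task (2,000 segments, ≈ 600 MB of features in float32), trained
for at most 25 epochs with patience 2 and min-delta 2e-3 — the
min-delta stops training once validation loss has plateaued, which
with these strongly separable classes happens well before epoch 25.
The reported score is the median held-out macro F1 over 3 training
seeds on the fixed dataset. The transfer benchmark trains a 3-class
generalized model on 250/80 segments per class, then compares transfer
retraining against from-scratch training with 30 training + 10
validation segments per class, median over 3 seeds, on the shared
100-per-class test set.

## Evaluation conventions

Confusion matrices have gold-standard rows and automated-classification
columns. Recall = diagonal / row total, PPV = diagonal / column total,
F1 = harmonic mean of the *unrounded* recall and PPV, macro F1 =
unweighted mean of per-class F1. Reported values are truncated (not
rounded) to two decimals — this convention is what reproduces the
published tables exactly (e.g. a PPV of 0.5688 prints as 0.56) — and
full-precision values are always retained. The printed "average"
recall and PPV of the source tables do not equal any standard
aggregate of the printed matrices and are not reproduced; the macro F1
is, in both tables.

## Known limitations

* Synthetic-only validation of classifier quality (see above).
* The exact layer hyperparameters of the original model are not
  recoverable; the defaults here are declared, not inferred.
* The EDF reader requires equal per-channel sampling rates; `.mef` and
  `.d` proprietary formats are unsupported by design.
* Detection is per-channel; no cross-channel event merging.
* Training is single-device, full-precision float32, CPU-oriented.
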