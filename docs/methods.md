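# Methods

## Problem and scope

The package classifies six activities of daily living — walking, walking
upstairs, walking downstairs, sitting, standing, laying — from
fixed-length windows of a waist-worn six-axis inertial sensor
(three accelerometer axes in g, three gyroscope axes in °/s, 50 Hz).
It implements the complete chain: raw-count conversion, precision
calibration, per-channel min–max normalization, sliding-window
segmentation, the stratified split protocol, a three-branch multi-kernel
CNN with feature fusion, its training schedule, the one-vs-rest metric
suite, a merged-data k-fold cross-validation, and a synthetic signal
generator that stands in for field recordings.

## Preprocessing

* **Unit conversion** divides integer counts by the LSB sensitivities
  (2048 counts/g, 16.4 counts/(°/s)) — the MPU-6050 at ±16 g / ±2000 °/s.
* **Precision calibration** rounds every value to 7 significant decimal
  digits (round-half-even), matching the scientific-notation
  serialization width so accelerometer and gyroscope entries have equal
  length. The operation is idempotent and property-tested as such.
* **Normalization** is per-channel min–max onto [−1, 1], fitted on the
  training portion only. Out-of-range test values are clipped so the
  bound holds literally; a constant channel is flagged degenerate and
  maps to 0. The choice to clip (rather than allow mild excursions) is a
  package decision; it is irrelevant on the synthetic data, where splits
  are exchangeable.
* **Segmentation**: window length `L = round(seconds × rate)`, stride
  `round(L × (1 − overlap))`; a window straddling an activity-label
  change is dropped rather than majority-labelled, keeping labels
  unambiguous. 2.56 s at 50 Hz gives the 128-sample public-dataset
  geometry; 3 s gives the 150-sample device geometry (900 features
  flattened).
* **Flattening** is channel-blocked — all AX samples, then AY, AZ, GX,
  GY, GZ — and exactly invertible.

## Split protocol

Per class: `n_test = round(0.3 n)`; from the remaining pool,
`ceil(0.2 pool)` windows form the verification set; the rest train.
Ceiling rounding is deliberate: it reproduces every published per-class
count (1,293/324/693 from a 2,310-window class) and the 1,471-window
verification hold-out from a 7,352-entry pool, where floor rounding
matches neither. The original report's overall device-data accounting
(9,702/4,158/1,941) is internally inconsistent with its own per-class
figures (which imply 1,944 verification windows); the per-class
(stratified) protocol is the one implemented, and `split_accounting`
exposes the arithmetic so the three-window discrepancy is visible rather
than hidden.

## Architecture

Each of the three zones applies three stride-1 convolutions
(32, 64, 128 filters; kernel 1, 3 or 5), each followed by batch
normalization, ReLU, and dropout (rate 0.3), then flattens. Design
choices on points the source description leaves open:

* **Padding** is "same", keeping all zones' flattened widths equal
  (`128 L` each, `384 L` concatenated), which makes the fusion balanced
  and matches the symmetric branch diagramming; at L = 150 the model has
  14,977,958 trainable parameters, verified in tests against an
  independent closed-form count.
* **No pooling layers** — only convolutions, flatten, and the FC head.
* **Batch-norm placement** is after each linear map, before ReLU.
* **Dropout placement**: the source states only that dropout was used
  between layers at rate 0.3. The default here applies it after each FC
  layer only; applying it after every zone convolution as well is
  available (`dropout_in_zones=True`) but proved to destabilize training
  at desk scale — with nine convolutional dropouts the verification
  accuracy plateaued around 0.8 and checkpoint selection degenerated,
  while FC-only dropout trains stably to >93% on the reference
  benchmark. FC-only is also the conventional placement for conv stacks
  that already carry batch normalization.
* **Initialization** is uniform fan-in, `U(±1/√fan_in)`, from a recorded
  seed; two builds with the same seed are bit-identical.

The engine itself (conv via k shifted GEMMs, batch norm, inverted
dropout, Adam) is written in numpy/float32 because no deep-learning
framework is available in the target environment; its gradients are
verified by finite differences in the development history and its
training behaviour by the separability and determinism tests.

## Training

Adam at 10⁻³; reduce-on-plateau (×0.5 after 10 stagnant verification
epochs) with a hard floor of 10⁻⁷; categorical cross-entropy on one-hot
labels; batch size 64 (a conventional default at this dataset scale,
unstated in the source); up to 1000 epochs with early stopping after 50
stagnant epochs, returning the parameter state of the best
verification-loss epoch. "Iterations" is read as epochs — with early
stopping the distinction is immaterial. Runs are deterministic given the
seeds (single-threaded BLAS): batch order, dropout masks and
initialization each draw from independent seeded streams.

## Metrics

Counts stay integers until the final percentage. Accuracy is the
multiclass diagonal fraction (the binary TP/TN form averaged one-vs-rest
is exposed separately as `one_vs_rest_accuracy`). Macro precision/recall
are unweighted means of per-class one-vs-rest values; a zero-denominator
class contributes 0 and is flagged. F1 defaults to the harmonic mean of
the two macros, as printed in the source formulas; the per-class-averaged
macro-F1 is provided as an alternative because the source's reported F1
values are not reproducible from its own macro values under either
formula exactly (97.64/97.46 → 97.55 by harmonic mean, vs 97.51
printed), so neither is asserted anywhere.

k-fold cross-validation pools all windows, deals them into k near-equal
folds (stratified by default; an unstratified "k equal parts" mode
exists), trains a fresh model per fold with 10% of the training part
held out for early stopping — the fold protocol's verification slice is
unstated in the source and recorded here — and reports per-fold, pooled
and mean accuracy.

## Synthetic data

The generator emulates the device study's protocol: 21 participants ×
6 activities × 110 non-overlapping 3-s windows at 50 Hz = 13,860 windows
of 900 features. Signals are built from a stated world fixed a priori:

* dynamic classes are gravity plus a 3-harmonic series at gait
  frequencies 1.8 / 1.4 / 2.2 Hz (walking / upstairs / downstairs) with
  distinct per-axis amplitude patterns and matching periodic gyroscope
  rates;
* sitting and standing share the y-down gravity orientation and differ
  only in mean noise scale and a small sway-amplitude offset (about a
  1.6× ratio). On top of this, every posture recording draws a
  per-recording lognormal "restlessness" gain (σ = 0.25) that scales its
  sway and noise: individuals differ in how still they hold a posture,
  so a fidgety sitter overlaps a calm stander. The overlap is at the
  recording level — within a recording the level is stationary and the
  discriminant stays learnable — which makes the sit/stand confusion
  irreducible and block-structured, reproducing the qualitative error
  structure reported for real data while the mean separation keeps the
  pair better than chance. (Pure mean-separation designs proved
  bimodal: fully learnable at 1.6×, complete collapse at ≤1.4×.)
* laying rotates gravity mostly onto the front axis;
* inter-subject variation is a multiplicative amplitude jitter
  ~N(1, 0.05²) per participant; each recording also jitters its gait
  frequency by 2% and draws random phases;
* noise is white Gaussian per channel plus a small random-walk baseline
  wander; an optional 5 Hz zero-phase Butterworth low-pass emulates the
  sensor's on-chip filter (off by default, since the analyzed device
  data were unfiltered).

What the generator does **not** model: transition segments between
activities, biomechanically realistic gait waveforms, sensor saturation,
orientation drift of the mounting. A green end-to-end test therefore
establishes that the pipeline, model and training loop work and that the
architecture can exploit multi-scale structure — not that the published
full-scale accuracies are reproduced; those require the external
datasets (see `examples/06_uci_reproduction.py`).

## Numerical choices

* float32 weights/activations; losses accumulated in float64.
* Batch-norm eps 10⁻⁵, momentum 0.1; inference uses running statistics.
* Cross-entropy clamps the true-class probability at 10⁻¹² .
* Softmax is shift-stabilized; prediction ties break to the lowest
  class index.
* Round-half-even at the 7th significant digit for calibration.
* Device-dialect serialization uses `%.7e`, giving round trips within
  10⁻⁷ absolute on unit-scale data.

## Known limitations

* The merged k-fold protocol normalizes on the pooled data (the merged
  protocol has no train/test boundary before folding); per-fold
  refitting would be stricter.
* Training at full published scale (7,352 windows × hundreds of epochs)
  takes hours on one CPU with this numpy engine; the shipped benchmarks
  are scaled down accordingly (1,200 windows, ≤50 epochs).
* Subject-wise (leave-participants-out) evaluation is not implemented;
  splits are window-stratified, matching the source protocol.
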