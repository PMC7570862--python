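# Methods

`harsdae` implements a complete recognition pipeline for wrist-worn
inertial-sensor streams: a synthetic study generator, sliding-window
segmentation, class rebalancing, a from-scratch stacked denoising
autoencoder (SDAE) classifier, and multiclass evaluation.  This note
records the model, its assumptions, the tunable parameters, the numerical
choices, and what the synthetic data can and cannot establish.

## The recognition problem

Twelve daily activities in three groups are distinguished from 6-channel
streams (tri-axial accelerometer in g, tri-axial gyroscope in deg/s,
102.4 Hz):

* **static** — standing, sleeping, watching TV: a sustained posture, i.e. a
  near-constant gravity direction plus sensor noise;
* **dynamic** — walking, running, sweeping: rhythmic movement, i.e. strong
  quasi-periodic oscillation around a posture;
* **transitional** — stand-to-sit, sit-to-stand, stand-to-walk,
  walk-to-stand, lie-to-sit, sit-to-lie: a short (seconds) monotone change
  of posture between two holds.

Transitional activities last ~15 s against ~5 min for the others, so their
window counts are ~5× smaller; this class imbalance is the central
difficulty the pipeline addresses.

## Segmentation and standardization

Streams are cut into windows of n = 512 samples (5 s at 102.4 Hz) with 50%
overlap (step = round(n·(1−overlap)), ties rounded away from zero;
trailing partial windows are discarded, and windows never span bout
boundaries).  Each window is flattened channel-block-wise,
`[acc_x(n), acc_y(n), acc_z(n), gyr_x(n), gyr_y(n), gyr_z(n)]`, giving
instances of length M = 6n = 3072.

Standardization maps every feature into [0, 1], as required by the
cross-entropy reconstruction loss: a per-feature z-score
x* = (x − μ)/σ followed by a min–max rescale of the z-values to [0, 1].
A z-score alone does not produce values in [0, 1], so the affine rescale
(using the fitting set's post-z minima/maxima) is applied on top; held-out
values outside the fitted range are clipped, and σ = 0 features map to the
midpoint 0.5.  Statistics come from whatever set the pipeline mode fits on
(see *Stage ordering* below).

The labelled set is split 6:2:2 into train/validation/test by a seeded
permutation with cut points at round(0.6·N) and round(0.8·N); a stratified
mode applies the cuts class by class.

## Rebalancing

Three equalization methods are provided, all deterministic under a seed:

* **random oversampling** (default): minority classes are grown to the
  majority count by uniform duplication with replacement; originals are
  always retained;
* **random undersampling**: majority classes are shrunk to the minority
  count by uniform sampling without replacement;
* **SMOTE**: synthetic minority points `x_new = x + r·(x_n − x)` with a
  single r ~ U[0,1) per point, where x is a uniformly drawn class instance
  and x_n one of its k nearest same-class neighbours (Euclidean; k defaults
  to 5, capped at class size − 1).  Every synthetic point therefore lies on
  the segment between its parents and inside the per-class bounding box.
  A printed formulation of this update adds the *scalar* Euclidean distance
  |x − x_n| to every component; that literal variant is kept behind
  `literal_distance=True` for fidelity experiments, but component-wise
  interpolation is the default because it is what nearest-neighbour
  interpolation means geometrically.

## The stacked denoising autoencoder

Each layer corrupts its input by masking noise (every component zeroed
independently with probability `a`, the denoising factor), encodes and
decodes with sigmoids,

    y = sigmoid(W1 x' + b1),   z = sigmoid(W2 y + b2),

and minimises the summed binary cross-entropy between the reconstruction z
and the **uncorrupted** input x.  Pretraining is greedy and layer-wise:
layer l+1 trains on the clean (uncorrupted) encodings of layer l's inputs,
and each layer re-corrupts its own input freshly at every mini-batch.
Fine-tuning appends a softmax head, drops corruption entirely, freezes the
decoders, and trains all encoder weights plus the head on categorical
cross-entropy like an ordinary MLP.

Defaults (the reference configuration):

| parameter | default | notes |
|---|---|---|
| hidden layers | 2 × 500 sigmoid units | input 3072 |
| denoising factor a | 0.5 | masking probability during pretraining only |
| pretraining rate | 1e−7 | only seeds initial values; deliberately tiny |
| fine-tuning rate | 0.01 | |
| iterations | 200 | full epochs, both phases |
| batch size | 64 | plain mini-batch gradient descent, no momentum |

Numerical and design choices:

* **Batch reduction.** The reconstruction loss is a *sum* over components;
  the same summation convention is kept over the mini-batch (gradient of
  the batch-summed loss), so the per-sample step size is independent of the
  batch size and the tiny pretraining rate and the 0.01 fine-tuning rate
  behave sensibly.  Loss traces are reported as per-sample means.
* **Model selection.** The validation set selects the optimal model:
  fine-tuning snapshots the parameters at the epoch with the highest
  validation accuracy and restores them at the end (`restore_best`,
  default on).  Plain gradient descent at a fixed rate can overshoot after
  converging; best-epoch restoration is the standard use of a validation
  set and makes the final model insensitive to the exact epoch count.
* **Initialisation.** Weights uniform in ±sqrt(6/(fan_in+fan_out))
  (Glorot), biases zero, all seeded.
* **Clipping.** ε = 1e−12 inside every log; prevents −∞ without measurable
  bias.  Softmax is computed shifted by the row maximum.
* **Determinism.** All randomness (init, shuffling, corruption masks)
  derives from one seed through `numpy.random.SeedSequence` children;
  identical config + data + seed gives identical final weights.
* **Divergence.** A non-finite loss aborts with a diagnostic naming the
  offending learning rate.
* Per an ambiguity in the original description, corruption is applied to
  each stacked layer's own input during that layer's pretraining (not only
  to the raw input), and decoders receive no gradient during fine-tuning.

## Evaluation

Per-class precision, recall and F1 come from one-vs-rest TP/FP/FN/TN counts
of the 12×12 confusion matrix, reported in percent; the per-class
"accuracy" column repeats recall, the convention of per-activity tables in
this field.  Zero denominators yield 0 with a warning.  Overall summaries
are micro-averaged (for single-label multiclass, micro precision = recall
= F1 = accuracy = trace/total, exactly) or support-weighted; both modes are
provided because published summary tables in this area are not always
explicit about which they use.

## Stage ordering and leakage

The default `mode="paper"` follows the reference procedure: segment →
resample (whole pooled set) → standardize (fit on the pooled set) → split
6:2:2 → pretrain → fine-tune → test.  Resampling before splitting lets
duplicated/synthetic minority instances appear on both sides of the split
and standardization statistics see the test data, which inflates test
scores for the minority classes; `mode="leakfree"` splits first, resamples
and fits the standardizer on the training portion only, and records the
reordering in the run manifest.  The default reproduces the reference
procedure; the leak-free mode is the methodologically sound alternative.
Whether the original procedure pooled or separated the repeats of each
activity before segmentation is not determinable, so the simulator exposes
bout repeats in the protocol without asserting either convention.

## The synthetic study generator

The real recordings behind this kind of study (10 subjects in a smart lab)
are not publicly deposited, so the package ships a generator that emulates
the protocol's *statistical* structure per activity:

* static: constant posture offset (gravity direction on the acc channels)
  plus Gaussian noise (acc σ 0.01–0.02 g, gyr σ 0.6–1.5 deg/s);
* dynamic: offset + per-channel sinusoid (walking 2 Hz, running 3 Hz,
  sweeping 1 Hz; acc amplitudes 0.25–0.85 g, gyr 40–150 deg/s; random
  phase) + noise;
* transitional: hold(start posture) → logistic ramp (2.5 s, centred
  mid-bout) → hold(end posture), with plateau noise (acc σ 0.03 g, gyr σ
  3 deg/s) larger than the static postures' — subjects fidget around a
  transition — so per-window variance orders static < transitional plateau
  < dynamic.  Each activity's hold postures are given slightly different
  wrist orientations (standing *about to sit* is not quiet standing), which
  keeps the twelve classes identifiable in principle.

The default protocol (10 subjects; one 300 s bout per continuous activity;
two hold–ramp–hold bouts with 15 s holds per transitional activity;
102.4 Hz) yields 1190 windows per continuous class and 240 per transitional
class — the ~5:1 imbalance (and roughly the absolute counts) characteristic
of such protocols.  The transitional bout count was set from the published
per-class sample totals (~60 s of data per subject per transitional class),
which imply far fewer recorded repetitions than the scripted "repeat 15
times"; the repeat count is a protocol parameter for anyone who prefers the
scripted reading.

What the generator does **not** emulate: biomechanical detail (gait
harmonics, tremor, sensor drift), between-subject variability (all subjects
share the activity models; only the noise and phases differ), and
within-class diversity of movement style.  Passing the end-to-end test
therefore shows that the pipeline — segmentation, rebalancing,
standardization, pretraining, fine-tuning, evaluation — is implemented
correctly and can recover a 12-class structure under realistic imbalance
and noise; it does not certify field accuracy on real recordings.

## Problem sizes used in tests and the acceptance script

Unit tests run on toy layers (≤ 10 units) and two-subject studies with
shortened bouts.  The end-to-end check uses the full default study
(8580 windows before oversampling, 14,280 after; 3072 features) with 5
pretraining epochs and 120 fine-tuning epochs in float32 — the pretraining
rate of 1e−7 changes the weights negligibly, so few pretraining epochs
suffice, and best-epoch restoration makes accuracy flat beyond ~100
fine-tuning epochs.  The repository's bar for that check is ≥ 90% test
accuracy on the default synthetic study.

## Known limitations

* Plain gradient descent only (no momentum/weight decay); convergence is
  slow and non-monotone near the optimum — mitigated by best-epoch
  restoration, not by a different optimizer, to stay faithful to the
  reference method.
* The literal scalar-distance SMOTE variant can leave the class bounding
  box; it exists only for fidelity comparisons.
* CSV is the single interchange format; very long studies are better
  generated in memory than round-tripped through CSV.
* Model files (.npz) store weights as little-endian float64 regardless of
  the training dtype.
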