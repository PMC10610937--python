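# Methods

This note documents the models, the data conventions, the training and
evaluation protocol, the synthetic-data generator, and the numerical and
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem and conventions

Pre-impact fall detection classifies the *descent* of a fall — the interval
from loss of balance (onset) to ground contact (impact) — from a waist-worn
IMU, early enough to act (e.g. inflate a wearable airbag). The warning
margin, `lead time = impact moment − detected moment`, is the quantity of
practical interest alongside trial-level sensitivity and specificity.

Internal conventions, applied by every reader on load:

* channels in fixed order `acc_x..z` (g), `gyr_x..z` (deg/s),
  `euler_x..z` (deg); a trace carries a 3/6/9-channel prefix of that order;
* sampling at 100 Hz (other rates are rejected rather than resampled —
  resampling is out of scope);
* frame ranges are half-open `[start, end)` and 0-based throughout. The fall
  phase is `[onset, impact)`; whether the source annotations treat the
  impact frame as inclusive is not derivable from the data itself, so the
  half-open choice is a documented convention, not an inference.
* acceleration-only traces in foreign conventions are aligned with an
  `AxisUnitMap` (axis permutation, sign flips, per-group unit scale, e.g.
  1/9.81 for m/s² → g). The correct orientation is device-specific, so the
  map is user-supplied; only the unit conversion has a safe default.

## Windowing and labels

Sliding windows of `window_frames = 50` (0.5 s) advance by
`step_frames = 10` (0.1 s); trailing frames that cannot fill a window are
dropped because the classifiers take fixed-size inputs. A window of a fall
trial is labeled *fall* when at least 40% of its frames lie inside the fall
phase ("at least" = `≥`). Windows of ADL trials are always *non-fall*, as
are fall-trial windows below the overlap threshold — including those
covering the impact spike, so the learned signature is the pre-impact
descent rather than the impact itself.

The 40% comparison is evaluated as an exact rational
(`count/window ≥ p/q`, with `p/q` recovered from the configured float via
`Fraction(...).limit_denominator(10⁶)`, i.e. 2/5 for 0.4), so the boundary
case "exactly 20 of 50 frames" labels *fall* regardless of float
representation.

A window's `end_time_s` is the timestamp of its last frame,
`(start + 50 − 1)/100`. This is also the *detected moment* when that window
triggers: a causal detector cannot act before the window is complete.

## The architecture zoo

All models consume `(50, C)` windows and emit 2-way softmax scores.
Convolutions use "same" padding, so only pools and strides change the
temporal length; conv order is conv → batch norm → ReLU.

* **conv_lstm** (benchmark): three Conv1D units (64 filters, kernel 7,
  stride 1, batch norm, ReLU, max-pool 2) then two LSTM layers (64 units,
  dropout 0.5), final-hidden-state → dense softmax. Variants: 9-axis,
  6-axis, and a kernel-3 version with one extra conv unit (the "narrower
  kernels, deeper stack" trade; its exact depth is not specified anywhere
  recoverable, so 4 units is the documented default).
* **vgg1d**: VGG16/19 stage layouts (2-2-3-3-3 / 2-2-4-4-4 convs, kernel 3,
  pool 2, widths 64→512), optionally with batch norm, with two 64-unit LSTM
  layers replacing the classic two-4096-dense head, and with a uniform
  64-filter override.
* **resnet1d**: bottleneck residual blocks (1×1 reduce, k×3 conv, 1×1
  expand; expand = 4 × reduce; shortcut is identity for *identity blocks*
  and a strided 1×1 projection for *convolutional blocks*; final ReLU after
  the add). ResNet50 follows the standard (3,4,6,3)-block layout with a
  `filter_scale` knob (ceil, minimum 1) and a uniform-64 option.

**ResNet24 from the VGG19 layout.** VGG19's five stages hold 16 conv layers
— an even count, which is why the 19-layer layout is the base — and each
*pair* of conv layers becomes one bottleneck block: stages of (2,2,4,4,4)
convs become (1,1,2,2,2) residual blocks, 8 blocks × 3 convs = 24 weighted
conv layers. Each stage opens with a stride-2 convolutional block standing
in for the VGG pool; remaining pairs are identity blocks. "Filters = 64" is
read as block *output* width 64 (reduce width 16), matching the 64-wide
feature maps of the benchmark.

**The lightweighting ladder.** Identity blocks never change tensor shapes,
so they can be deleted without touching any downstream dimension.
`lighten(spec, k)` removes k of them, deepest stage first, giving
ResNet21/18/15 (the published figures of the ladder are graphical only, so
the ladder is defined operationally and shipped as versioned YAML configs;
any other removal order can be configured). The final step to 14 conv
layers removes one more weighted layer that cannot be an identity block
(none remain): the *entry* block's 1×1 reduce conv. With a ≤9-channel
input that conv compresses nothing, and removing it strictly decreases the
parameter count — whereas slimming a deep 64-channel block would *increase*
it, since the kernel-3 conv would then read the wide input directly. The
result, `tinyfallnet`, has 31,826 parameters.

**Parameter accounting.** Closed forms: conv `C_in·k·C_out + C_out`, LSTM
`4·((C_in+H)·H + H)`, dense `C_in·C_out + C_out`, batch norm `2C` trainable
(running mean/variance are buffers, counted separately on request). Memory
is reported as `trainable × 4` bytes (float32) and documented as a lower
bound on any saved-file size — serialized checkpoints add container and
optimizer state, so externally reported memory figures are compared as
orderings and ratios, never as exact megabytes. The closed-form count is verified
against an independent census of the engine's allocated weight arrays for
every shipped variant.

## The training engine

No deep-learning framework is part of the dependency set; training runs on
a purpose-built numpy engine (`fallnet.nn`) implementing exactly the layers
the zoo needs, with analytic reverse-mode gradients verified against central
differences (tolerance 1e-6) layer by layer and through a residual network
end to end. Design points:

* im2col convolutions ("same" padding, TensorFlow pad-split convention);
  valid max pooling with stride = pool size; inverted dropout; batch norm
  with momentum-0.9 running statistics for evaluation mode.
* LSTM with gate order i, f, g, o, zero initial state, full-window BPTT.
* He-normal initialization; Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7). The
  protocol source states batch size, epochs, early stopping and threshold
  but not the optimizer; Adam at its conventional rate is this package's
  choice and is exposed in `TrainConfig`.
* float64 arithmetic throughout — problem sizes are small enough that
  clarity and gradient-check fidelity beat the ~2× speed of float32.

Training protocol (defaults in `TrainConfig`): subject-wise 80/20
train/test split (`round(0.8·n)` subjects train, rest test, seeded
shuffle — 32 subjects split 26/6), validation as a random 20% of training
*windows* (the protocol specifies only a validation ratio, not its
granularity; subject-agnostic sampling is the documented reading), batch
64, ≤200 epochs, early stopping after 20 epochs without validation-accuracy
improvement with best-weights restoration (restoring is what makes the
stopping rule meaningful), softmax threshold 0.7 with ties detecting (`≥`).
No class re-weighting or oversampling is applied by default. Runs are bit-
reproducible given the seed. Degenerate single-class training data is an
error, and undefined rates (zero denominators) report NA, never 0.

## Evaluation

Metrics are defined over whole trials: TP = fall trials with at least one
window at/above threshold ("classified as a fall for the first time" is
read as "at least one window detected"); FN = fall trials with none; FP/TN
analogously for ADL trials. Sensitivity, specificity and accuracy follow
the standard percentage forms. Lead times are collected per detected fall;
negative values (detection after impact) are kept and flagged. The reported
spread is the population SD (a single lead time has spread 0, not NA).

Per-task × per-subject *fraction tables* (`correct/total` cells, NA for
skipped tasks) are pooled by summing numerators and denominators over
non-NA cells. The two bundled reference tables for the elderly-ADL
evaluation pool to 562/640 (87.81%) under the single-window rule and
627/640 (97.97%) under the consecutive-window rule; the prose of the source
evaluation elsewhere quotes 566/640 (88.43%) for the former — an internal
inconsistency in that source — and this package reproduces the table
aggregation.

## The online detector

`DetectorConfig` defaults: window 50, step 1, threshold 0.7, three
consecutive above-threshold windows required. A *run* is strictly
consecutive window positions; any sub-threshold window resets the counter.
The detection moment is the end time of the *confirming* (third) window —
the earliest causally defensible instant. Whether the original modified
rule timestamps the first or third window of the run is unstated; the
third-window choice is documented and consistent with the detected-moment
convention above. With `consecutive_required = 1` and step 10 the detector
reduces exactly to the plain trial classifier (a tested property), and on
any fixed score sequence the 3-window rule can only delay detections and
only remove false positives relative to the 1-window rule — the mechanism
behind the specificity gain. Streaming (frame-at-a-time) execution scores
the same windows in the same order as batch execution and stops scoring
once confirmed.

## Synthetic cohorts

The generator is phenomenological — piecewise kinematic templates plus
Gaussian noise — not biomechanical. Its job is to carry the statistical
structure the pipeline assumes, so that windowing, training, evaluation and
the detector are exercised end to end:

* **ADLs**: static stance (gravity + noise), walk/jog (gravity + gait
  sinusoids at 1.8–2.2 / 2.5–3.2 Hz with activity-specific amplitudes),
  sit-stand/bend (raised-cosine orientation transitions with bounded
  acceleration excursions). ADL acceleration magnitude stays below the
  minimum impact peak by construction.
* **Falls**: a prefall ADL segment (2.5–3.5 s), a descent of 300–700 ms in
  which the magnitude ramps from ~1 g to below the 0.3 g free-fall floor
  while the tilt axis surges (90–160 deg/s, direction-specific sign and
  axis), an impact spike whose peak equals a sampled 3–8 g value exactly,
  and a lying-still tail with rotated gravity. The onset/impact annotation
  brackets the descent by construction.
* Euler channels are synthesized from the orientation template directly
  rather than integrated from the gyro — this avoids drift bookkeeping and
  costs nothing because no downstream component assumes gyro/Euler
  consistency.
* Per-subject amplitude/frequency offsets (±15% / ±10%) make subject-wise
  splitting meaningful; an `elderly_like` flag adds low-frequency sway and
  slower transitions to exercise the false-positive behavior of the
  decision rules qualitatively.
* Determinism: child seeds derive from (seed, subject, task, trial), so
  cohorts are bit-reproducible and single trials do not depend on cohort
  size.

Default cohort: 8 subjects × (5 ADL + 4 fall kinds) × 2 trials = 144
trials, ≈7,700 windows — large enough for a meaningful subject-wise split,
small enough that a full train-and-evaluate cycle takes well under a minute
on one CPU (the acceptance run caps epochs at 60 with patience 10; in
practice early stopping fires near epoch 15).

**What passing tests do and do not show.** The synthetic free-fall dip is
cleanly separable from the ADL repertoire, so near-perfect trial metrics on
held-out synthetic subjects demonstrate that the pipeline is wired
correctly — labels, splits, training, thresholding, lead times — not that
the architecture would reach any particular accuracy on real falls. Real
IMU data add sensor artifacts, inter-subject variability far beyond ±15%,
and fall modes the templates do not model; readers with access to real
annotated cohorts should expect lower numbers there.

## Known limitations

* No resampling of non-100 Hz data; no Euler-angle computation from raw
  gyro; no downloader for external datasets.
* The numpy engine is single-threaded and CPU-bound; the large zoo members
  (full-width VGG16, unscaled ResNet50) are buildable and countable but
  impractical to train with it.
* No hyperparameter search, cross-validation beyond the single subject-wise
  split, threshold calibration, quantization or distillation.
* The fraction-table layout assumes one table per decision rule with
  subjects as columns; other published layouts need reshaping by the user.
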