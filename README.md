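# fallnet — pre-impact fall detection from wearable IMU streams

`fallnet` is a library (plus a thin CLI) for **pre-impact fall detection**:
classifying a fall *during the descent*, before ground contact, from a
waist-worn inertial measurement unit (IMU) — the detection problem behind
wearable airbags, where the warning margin before impact ("lead time")
decides whether protection can deploy at all. It is aimed at researchers in
human-movement analysis who need the full pipeline — trial ingestion,
sliding-window labeling, compact 1-D networks, trial-level evaluation, and
an online decision rule — reproducible on a laptop CPU without any dataset
download.

## What it does

**Data model.** A trial is a 100 Hz multichannel trace (3-axis acceleration
in g, angular velocity in deg/s, Euler angles in deg; 3/6/9-channel
prefixes). Fall trials carry an annotation `[onset, impact)`: the descent
from loss of balance to ground contact. Traces from foreign sensor
conventions (e.g. m/s², rotated axes) are aligned with a configurable
axis/unit map.

**Windowing.** Sliding windows of 50 frames (0.5 s) at step 10 (0.1 s). A
window of a fall trial is labeled *fall* when at least 40% of its frames lie
inside the fall phase; every other window — including the impact spike — is
*non-fall*, so the classifier learns the descent, not the crash.

**Model zoo.** Declarative specs for three 1-D families: the conv+LSTM
benchmark (3 × Conv1D(64, k=7) units + 2 × LSTM(64)), VGG16/19 variants
(batch norm / LSTM / uniform 64 filters), and bottleneck residual networks —
ResNet50 with filter scaling, and ResNet24 derived from the VGG19 layout by
replacing each pair of conv layers with one residual block
(reduce → conv → expand widths, expand = 4 × reduce). Removing the
shape-preserving *identity blocks* one at a time gives the lightweighting
ladder ResNet24 → 21 → 18 → 15, and dropping the entry block's 1×1 reduce
conv yields the final 14-conv-layer model, **tinyfallnet** (31,826
parameters, 0.12 MiB at float32 — a quarter of the benchmark's 128,130).
Parameter counts come from layer closed forms and are cross-checked against
the training engine's allocated arrays.

**Training & evaluation.** A compact numpy engine (Conv1D / batch norm /
max pool / LSTM / dense, Adam) trains any spec with the standard protocol:
subject-wise 80/20 split, batch 64, ≤200 epochs, early stopping on
validation accuracy (patience 20), threshold 0.7 on the softmax fall
probability. Metrics are **trial-level**:

    sensitivity = TP/(TP+FN)·100   specificity = TN/(FP+TN)·100
    accuracy    = (TP+TN)/total·100    lead time = impact − detected moment

where a fall trial is TP if *any* window crosses the threshold and an ADL
trial is FP if any does.

**Online detector.** The modified rule steps windows by 1 frame and requires
**three consecutive** above-threshold windows before declaring a fall, so a
transient fall-like window inside an unsteady ADL no longer raises an alarm.
Batch and frame-at-a-time streaming execution are output-identical.

**Synthetic cohorts.** A seeded generator emulates annotated fall trials
(pre-impact free-fall dip, impact spike, lying tail) and ADL trials (stance,
gait, transitions) with per-subject kinematic offsets, so the whole pipeline
is testable end to end without external data.

## Worked example

```bash
python examples/train_and_evaluate.py
```

```
train on ['SYN02', 'SYN03', 'SYN04', 'SYN05', 'SYN06'], test on ['SYN01']
stopped after 12 epochs; best validation accuracy 0.9980
trials: 4 fall / 5 ADL
TP=4 FP=0 TN=5 FN=0
sensitivity: 100.00%
specificity: 100.00%
accuracy:    100.00%
lead time:   215.0 ± 53.2 ms (n=4)
```

Every fall trial of the held-out subject was detected on average 215 ms
before ground impact, and no ADL trial raised an alarm. The other scripts in
`examples/` each demonstrate one capability: `simulate_cohort.py`,
`window_labeling.py`, `model_zoo_tour.py`, `online_detection.py`,
`foreign_sensor_alignment.py`.

The same pipeline is scriptable from a shell:

```bash
fallnet simulate --out cohort/ --n-subjects 8 --seed 0
fallnet train --data cohort/ --model tinyfallnet --out ckpt --seed 0
fallnet evaluate --model-ckpt ckpt --data cohort/
fallnet detect --model-ckpt ckpt --trace cohort/SYN01_F_FORWARD_T01.csv \
               --annotations cohort/annotations.csv
fallnet aggregate-table src/fallnet/data/elderly_adl_fractions_consecutive_window.csv
```

## Layout

```
src/fallnet/      io, windowing, zoo (architectures), nn (engine),
                  training, evaluation, detector, synthetic, cli, reference
src/fallnet/configs/   one YAML per shipped architecture variant
src/fallnet/data/      bundled elderly-ADL fraction tables (CSV)
examples/         one narrative script per capability
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   models, protocol, generator design, limitations
```
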