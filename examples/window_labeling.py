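"""Cut one fall trial into sliding windows and label them.

Windows of 50 frames (0.5 s) advance by 10 frames; a window becomes 'fall'
when at least 40% of its frames lie inside the annotated descent phase.
"""

from fallnet import SimConfig, WindowingConfig, segment, simulate_fall
from fallnet.windowing import FALL, label_window

sim = simulate_fall("walk", "forward", seed=3,
                    cfg=SimConfig(fall_duration_ms=(500.0, 500.0)))
ann = sim.annotation
print(f"trial: {sim.trace.n_frames} frames; fall phase "
      f"[{ann.onset_frame}, {ann.impact_frame}) = "
      f"{(ann.impact_frame - ann.onset_frame) * 10} ms of descent")

cfg = WindowingConfig()  # 50 / 10 / 0.4
windows = segment(sim.trace, cfg)
labels = [label_window(w, ann, cfg) for w in windows]
print(f"{len(windows)} windows, {labels.count(FALL)} labeled fall:")
for w, label in zip(windows, labels):
    if label == FALL:
        inside = min(w.start_frame + 50, ann.impact_frame) - max(w.start_frame, ann.onset_frame)
        print(f"  start {w.start_frame:4d}  end {w.end_time_s:5.2f} s  "
              f"{inside}/50 frames in phase")
print("every other window (including the impact spike itself) is non-fall;")
print("the classifier learns the pre-impact descent, not the impact.")
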