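"""Sliding-window segmentation and fall/non-fall labeling.

Traces are cut into fixed-length windows (default 50 frames = 0.5 s at
100 Hz) advanced by a fixed step (default 10 frames = 0.1 s).  A window of a
fall trial is labeled ``fall`` when at least 40% of its frames lie inside the
annotated fall phase ``[onset, impact)``; every other window — including all
windows of ADL trials — is ``non_fall``.  Trailing frames that do not fill a
whole window are discarded (the classifiers take fixed-size inputs).

The 40% threshold is compared as an exact rational (``5·count ≥ 2·window``
for the default) so the boundary case "exactly 40%" labels ``fall``
regardless of float representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .io import (
    ChannelSelection,
    FallAnnotation,
    SensorTrace,
    is_fall_task,
    lookup_annotation,
    select_channels,
)

FALL = "fall"
NON_FALL = "non_fall"


@dataclass(frozen=True)
class WindowingConfig:
    """Window length, step, and minimum in-phase fraction for a fall label."""

    window_frames: int = 50
    step_frames: int = 10
    min_fall_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.window_frames < 1:
            raise ConfigError("window_frames must be >= 1")
        if not 1 <= self.step_frames <= self.window_frames:
            raise ConfigError("step_frames must be in [1, window_frames]")
        if not 0 < self.min_fall_fraction <= 1:
            raise ConfigError("min_fall_fraction must be in (0, 1]")

    @property
    def fraction_exact(self) -> Fraction:
        """The label threshold as an exact rational (0.4 → 2/5)."""
        return Fraction(self.min_fall_fraction).limit_denominator(10**6)


@dataclass(frozen=True)
class LabeledWindow:
    """One fixed-length window with its source identity and class label."""

    source: tuple[str, str, int]
    start_frame: int  # in the trace's frame_index coordinate
    values: np.ndarray  # (window_frames, C)
    label: str | None  # FALL / NON_FALL / None (not yet labeled)
    end_time_s: float  # timestamp of the window's last frame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise DataError(f"window at frame {self.start_frame} has non-finite values")


def segment(trace: SensorTrace, cfg: WindowingConfig) -> list[LabeledWindow]:
    """Cut a trace into unlabeled windows at 0, step, 2·step, ...

    Windows never extend past the trace end; a trace shorter than one window
    yields an empty list with a warning.  For a length-``N`` trace the window
    count is ``floor((N - window) / step) + 1``.
    """
    n = trace.n_frames
    w = cfg.window_frames
    if n < w:
        warnings.warn(
            f"trial {trace.source}: {n} frames < window of {w}; no windows",
            stacklevel=2,
        )
        return []
    first = int(trace.frame_index[0])
    out = []
    for offset in range(0, n - w + 1, cfg.step_frames):
        end_time = (first + offset + w - 1) / trace.sample_rate_hz
        out.append(
            LabeledWindow(
                source=trace.source,
                start_frame=first + offset,
                values=trace.samples[offset : offset + w],
                label=None,
                end_time_s=end_time,
            )
        )
    return out


def label_window(
    window: LabeledWindow,
    annotation: FallAnnotation | None,
    cfg: WindowingConfig,
) -> str:
    """Apply the minimum-fall-fraction rule to one window.

    The window covers frames ``[start, start + window_frames)``; the count of
    those frames inside ``[onset, impact)`` is an interval overlap.  ADL
    windows (no annotation) are always ``non_fall``.
    """
    if annotation is None:
        return NON_FALL
    w = cfg.window_frames
    lo = max(window.start_frame, annotation.onset_frame)
    hi = min(window.start_frame + w, annotation.impact_frame)
    count = max(0, hi - lo)
    return FALL if Fraction(count, w) >= cfg.fraction_exact else NON_FALL


@dataclass(frozen=True)
class TrialWindows:
    """All windows of one trial, in start-frame order."""

    source: tuple[str, str, int]
    windows: tuple[LabeledWindow, ...]
    is_fall_trial: bool
    annotation: FallAnnotation | None
    sample_rate_hz: float

    @property
    def n_fall_windows(self) -> int:
        return sum(1 for w in self.windows if w.label == FALL)


@dataclass
class WindowDataset:
    """Labeled windows grouped per trial, in deterministic order."""

    trials: list[TrialWindows] = field(default_factory=list)

    @property
    def windows(self) -> list[LabeledWindow]:
        return [w for t in self.trials for w in t.windows]

    def __len__(self) -> int:
        return sum(len(t.windows) for t in self.trials)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into ``X (N, window, C)`` and ``y (N,)`` with fall = 1."""
        ws = self.windows
        if not ws:
            raise DataError("dataset has no windows")
        x = np.stack([w.values for w in ws]).astype(np.float64)
        y = np.array([1 if w.label == FALL else 0 for w in ws], dtype=np.int64)
        return x, y

    def subject_ids(self) -> list[str]:
        return sorted({t.source[0] for t in self.trials})

    def subset_subjects(self, subjects: Iterable[str]) -> "WindowDataset":
        keep = set(subjects)
        return WindowDataset([t for t in self.trials if t.source[0] in keep])

    def manifest(self):
        """Per-window provenance table (subject, task, trial, start, label)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "subject_id": w.source[0],
                    "task_id": w.source[1],
                    "trial_id": w.source[2],
                    "start_frame": w.start_frame,
                    "end_time_s": w.end_time_s,
                    "label": w.label,
                }
                for w in self.windows
            ]
        )


def build_dataset(
    traces: Sequence[SensorTrace],
    annotations: Mapping,
    cfg: WindowingConfig = WindowingConfig(),
    selection: ChannelSelection | str | None = None,
) -> WindowDataset:
    """Segment and label a cohort of traces, grouped per trial.

    Trials are ordered by (subject, task, trial) and windows by start frame,
    so the output is deterministic.  A fall-task trace without an annotation
    is a data error (it could silently train as all-non-fall otherwise).
    """
    dataset = WindowDataset()
    for trace in sorted(traces, key=lambda t: t.source):
        if selection is not None:
            trace = select_channels(trace, selection)
        ann = lookup_annotation(annotations, trace)
        if ann is None and is_fall_task(trace.task_id):
            raise DataError(f"fall trial {trace.source} has no annotation")
        if ann is not None:
            ann.check_within(trace)
        windows = segment(trace, cfg)
        labeled = tuple(
            LabeledWindow(
                source=w.source,
                start_frame=w.start_frame,
                values=w.values,
                label=label_window(w, ann, cfg),
                end_time_s=w.end_time_s,
            )
            for w in windows
        )
        dataset.trials.append(
            TrialWindows(
                source=trace.source,
                windows=labeled,
                is_fall_trial=ann is not None,
                annotation=ann,
                sample_rate_hz=trace.sample_rate_hz,
            )
        )
    return dataset
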