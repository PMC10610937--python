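"""Online fall detector with a consecutive-window confirmation rule.

The plain trial classifier declares a fall at the first window whose softmax
fall probability crosses the threshold.  Elderly movement is less balanced
than young movement, so momentary "fall-like" windows inside ADLs inflate
false alarms.  The modified decision rule densifies the window stream (step
1 frame instead of 10) and requires ``consecutive_required`` successive
above-threshold windows before declaring a fall: a single transient window no
longer triggers, which trades a small detection delay for a large specificity
gain.  Any sub-threshold window resets the run.

The detector runs in two equivalent modes: batch (whole trace) and streaming
(frame at a time); both produce the same detection, frame for frame.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError
from .io import FallAnnotation, SensorTrace, select_channels
from .windowing import WindowingConfig, segment


@dataclass(frozen=True)
class DetectorConfig:
    """Modified decision rule: dense stepping + run-length confirmation."""

    window_frames: int = 50
    step_frames: int = 1
    consecutive_required: int = 3
    threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.consecutive_required < 1:
            raise ConfigError("consecutive_required must be >= 1")
        if self.step_frames < 1:
            raise ConfigError("step_frames must be >= 1")
        if not 0 < self.threshold < 1:
            raise ConfigError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class DetectionResult:
    """Detection moment (confirming window's end time) plus the score trace."""

    detection_moment_s: float | None
    window_end_times_s: tuple[float, ...]
    window_scores: tuple[float, ...]

    @property
    def detected(self) -> bool:
        return self.detection_moment_s is not None


def detect_from_scores(
    scores: Sequence[float],
    end_times: Sequence[float],
    cfg: DetectorConfig,
) -> float | None:
    """Pure decision rule on a fixed score sequence.

    Returns the end time of the k-th window of the first run of
    ``consecutive_required`` windows all scoring ≥ threshold, else None.
    """
    run = 0
    for score, t in zip(scores, end_times):
        run = run + 1 if score >= cfg.threshold else 0
        if run >= cfg.consecutive_required:
            return float(t)
    return None


def detect(
    model,
    trace: SensorTrace,
    cfg: DetectorConfig = DetectorConfig(),
) -> DetectionResult:
    """Run the confirmation rule over a whole trace (batch mode).

    The trace is restricted to the model's input channels, cut into windows
    at ``step_frames``, scored in one pass, and the run rule applied.
    """
    trace = select_channels(trace, _selection_for(model, trace))
    windows = segment(
        trace,
        WindowingConfig(
            window_frames=cfg.window_frames,
            step_frames=cfg.step_frames,
            min_fall_fraction=0.4,
        ),
    )
    if not windows:
        return DetectionResult(None, (), ())
    values = np.stack([w.values for w in windows])
    scores = model.fall_probability(values)
    end_times = tuple(w.end_time_s for w in windows)
    moment = detect_from_scores(scores, end_times, cfg)
    return DetectionResult(moment, end_times, tuple(map(float, scores)))


def _selection_for(model, trace: SensorTrace):
    from .io import ChannelSelection

    need = model.spec.input_channels
    if trace.n_channels < need:
        raise ConfigError(
            f"model needs {need} channels; trace has {trace.n_channels}"
        )
    return ChannelSelection.for_channels(need)


class StreamingDetector:
    """Frame-at-a-time detector, output-identical to batch :func:`detect`.

    Keeps a rolling buffer of the last ``window_frames`` frames; every
    ``step_frames``-th completed window is scored and fed to the run counter.
    ``push`` returns the detection moment (s) on the confirming frame and
    None otherwise; further frames after a detection are ignored.
    """

    def __init__(self, model, cfg: DetectorConfig = DetectorConfig(),
                 sample_rate_hz: float = 100.0, first_frame_index: int = 0) -> None:
        self.model = model
        self.cfg = cfg
        self.sample_rate_hz = sample_rate_hz
        self._buffer: deque[np.ndarray] = deque(maxlen=cfg.window_frames)
        self._frames_seen = 0
        self._first = first_frame_index
        self._run = 0
        self.detection_moment_s: float | None = None
        self.scores: list[float] = []

    def push(self, frame: np.ndarray) -> float | None:
        if self.detection_moment_s is not None:
            return self.detection_moment_s
        need = self.model.spec.input_channels
        frame = np.asarray(frame, dtype=float)[:need]
        self._buffer.append(frame)
        self._frames_seen += 1
        w = self.cfg.window_frames
        if self._frames_seen < w or (self._frames_seen - w) % self.cfg.step_frames:
            return None
        window = np.stack(self._buffer)[None, :, :]
        score = float(self.model.fall_probability(window)[0])
        self.scores.append(score)
        self._run = self._run + 1 if score >= self.cfg.threshold else 0
        if self._run >= self.cfg.consecutive_required:
            end_frame = self._first + self._frames_seen - 1
            self.detection_moment_s = end_frame / self.sample_rate_hz
        return self.detection_moment_s


def lead_time_online(
    detection_moment_s: float | None,
    annotation: FallAnnotation,
    sample_rate_hz: float = 100.0,
) -> float | None:
    """Lead time (ms) for an online detection; None when undetected.

    Negative values flag detections after impact.
    """
    if annotation is None:
        raise DataError("lead time requires a fall annotation")
    if detection_moment_s is None:
        return None
    return (annotation.impact_frame / sample_rate_hz - detection_moment_s) * 1000.0
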