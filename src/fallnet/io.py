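"""Core IMU data types and trial-table input/output.

A *trial* is one recording of a subject performing a task: an ordered table of
sensor frames sampled at a fixed rate (100 Hz for KFall-style data).  Channels
follow a fixed order and unit convention:

================  =========  ========
channel group     channels   units
================  =========  ========
acceleration      acc_x/y/z  g
angular velocity  gyr_x/y/z  deg/s
orientation       euler_x/y/z  deg
================  =========  ========

Traces carry 3, 6 or 9 channels — always a prefix of that order (acceleration
only, acceleration+gyro, or the full 9-axis IMU).  Fall trials additionally
carry a :class:`FallAnnotation`, the pair of frame indices bounding the fall
phase (loss of balance → ground contact).  Frame ranges are half-open
``[start, end)`` throughout the package.

Readers normalize external data to the internal units on load; traces from
sensors with other conventions (e.g. m/s² acceleration, rotated axes) are
aligned with :func:`convert_axes_units` and a user-supplied
:class:`AxisUnitMap`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

#: canonical channel order; a trace uses a prefix of this list
CHANNEL_NAMES = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "euler_x", "euler_y", "euler_z",
)

_VALID_CHANNEL_COUNTS = (3, 6, 9)

#: KFall-style fall tasks are coded F01..F15; synthetic fall codes also start
#: with "F".  Everything else is an activity of daily living (ADL).


def is_fall_task(task_id: str) -> bool:
    """True when a task code denotes a fall trial (code starts with ``F``)."""
    return str(task_id).upper().startswith("F")


@dataclass(frozen=True)
class SensorTrace:
    """One trial's multichannel IMU time series.

    ``samples`` is an ``(n_frames, n_channels)`` float array in the canonical
    channel order; ``frame_index`` gives each row's frame number (strictly
    increasing by 1, typically but not necessarily starting at 0).
    """

    subject_id: str
    task_id: str
    trial_id: int
    sample_rate_hz: float
    samples: np.ndarray
    frame_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise DataError("samples must be a 2-D (frames x channels) array")
        if samples.shape[0] < 1:
            raise DataError("a trace needs at least one frame")
        if samples.shape[1] not in _VALID_CHANNEL_COUNTS:
            raise DataError(
                f"channel count must be one of {_VALID_CHANNEL_COUNTS}, "
                f"got {samples.shape[1]}"
            )
        if not np.isfinite(samples).all():
            raise DataError("samples contain non-finite values")
        if self.sample_rate_hz <= 0:
            raise DataError("sample_rate_hz must be positive")
        if int(self.trial_id) < 1:
            raise DataError("trial_id must be >= 1")
        if self.frame_index is None:
            frame_index = np.arange(samples.shape[0], dtype=np.int64)
        else:
            frame_index = np.asarray(self.frame_index, dtype=np.int64)
            if frame_index.shape != (samples.shape[0],):
                raise DataError("frame_index length must match samples")
            if samples.shape[0] > 1 and not (np.diff(frame_index) == 1).all():
                raise DataError(
                    f"frame counter of trial {self.source} is not contiguous"
                )
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "frame_index", frame_index)

    # -- convenience -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_hz

    @property
    def source(self) -> tuple[str, str, int]:
        """(subject_id, task_id, trial_id) identity triple."""
        return (self.subject_id, self.task_id, int(self.trial_id))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return CHANNEL_NAMES[: self.n_channels]

    def acc_magnitude(self) -> np.ndarray:
        """Euclidean norm of the acceleration vector per frame, in g."""
        return np.linalg.norm(self.samples[:, :3], axis=1)


@dataclass(frozen=True)
class FallAnnotation:
    """Fall-phase bounds: onset (loss of balance) and impact (ground contact).

    Both are frame indices in the trace's ``frame_index`` coordinate; the fall
    phase is the half-open range ``[onset_frame, impact_frame)``.
    """

    onset_frame: int
    impact_frame: int

    def __post_init__(self) -> None:
        if not self.onset_frame < self.impact_frame:
            raise DataError(
                f"fall onset ({self.onset_frame}) must precede impact "
                f"({self.impact_frame})"
            )

    def check_within(self, trace: SensorTrace) -> None:
        lo = int(trace.frame_index[0])
        hi = int(trace.frame_index[-1])
        if self.onset_frame < lo or self.impact_frame > hi + 1:
            raise DataError(
                f"annotation [{self.onset_frame}, {self.impact_frame}) outside "
                f"frame range [{lo}, {hi}] of trial {trace.source}"
            )


@dataclass(frozen=True)
class ChannelSelection:
    """Select the leading acceleration / IMU channel prefix of a trace."""

    mode: str = "imu6"  # acc3 | imu6 | imu9

    _COUNTS = {"acc3": 3, "imu6": 6, "imu9": 9}

    def __post_init__(self) -> None:
        if self.mode not in self._COUNTS:
            raise ConfigError(f"unknown channel selection mode {self.mode!r}")

    @property
    def n_channels(self) -> int:
        return self._COUNTS[self.mode]

    @classmethod
    def for_channels(cls, n: int) -> "ChannelSelection":
        for mode, count in cls._COUNTS.items():
            if count == n:
                return cls(mode)
        raise ConfigError(f"no selection mode for {n} channels")


def select_channels(trace: SensorTrace, sel: ChannelSelection | str) -> SensorTrace:
    """Restrict a trace to its leading 3/6/9 channels (order preserved)."""
    if isinstance(sel, str):
        sel = ChannelSelection(sel)
    if sel.n_channels > trace.n_channels:
        raise ConfigError(
            f"selection {sel.mode!r} needs {sel.n_channels} channels but the "
            f"trace has {trace.n_channels}"
        )
    if sel.n_channels == trace.n_channels:
        return trace
    return replace(
        trace,
        samples=trace.samples[:, : sel.n_channels].copy(),
        frame_index=trace.frame_index,
    )


@dataclass(frozen=True)
class AxisUnitMap:
    """Axis permutation, sign flips, and per-group unit rescaling.

    Applied independently to each 3-channel group: target axis ``i`` receives
    ``signs[i] * unit_scale[group] * source axis permutation[i]``.  Used to
    align foreign sensor conventions (e.g. acceleration-only traces recorded
    in m/s² with a different axis order) with the package's internal one.
    """

    permutation: tuple[int, int, int] = (0, 1, 2)
    signs: tuple[int, int, int] = (1, 1, 1)
    unit_scale: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if sorted(self.permutation) != [0, 1, 2]:
            raise ConfigError("permutation must be a bijection of (0, 1, 2)")
        if any(s not in (-1, 1) for s in self.signs):
            raise ConfigError("signs must be +/-1 per axis")
        if any(s <= 0 for s in self.unit_scale):
            raise ConfigError("unit_scale factors must be positive")

    def inverse(self) -> "AxisUnitMap":
        inv_perm = [0, 0, 0]
        inv_sign = [1, 1, 1]
        for tgt, src in enumerate(self.permutation):
            inv_perm[src] = tgt
            inv_sign[src] = self.signs[tgt]
        return AxisUnitMap(
            permutation=tuple(inv_perm),
            signs=tuple(inv_sign),
            unit_scale=tuple(1.0 / s for s in self.unit_scale),
        )


def gravity_units_map() -> AxisUnitMap:
    """Default map for acceleration-only traces recorded in m/s².

    Divides by standard gravity so acceleration lands in g; axis order and
    signs are identity by default and must be overridden when the source
    sensor's orientation differs (the true orientation of long-term-monitoring
    datasets is device-specific and user-supplied).
    """
    return AxisUnitMap(unit_scale=(1.0 / 9.81,))


def convert_axes_units(trace: SensorTrace, map_: AxisUnitMap) -> SensorTrace:
    """Apply an :class:`AxisUnitMap` group-wise; metadata and length unchanged."""
    n_groups = trace.n_channels // 3
    if len(map_.unit_scale) not in (1, n_groups):
        raise ConfigError(
            f"unit_scale has {len(map_.unit_scale)} factors for a trace with "
            f"{n_groups} channel groups"
        )
    scales = map_.unit_scale * n_groups if len(map_.unit_scale) == 1 else map_.unit_scale
    out = np.empty_like(trace.samples)
    for g in range(n_groups):
        for i in range(3):
            out[:, 3 * g + i] = (
                map_.signs[i] * scales[g] * trace.samples[:, 3 * g + map_.permutation[i]]
            )
    return replace(trace, samples=out, frame_index=trace.frame_index)


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableDialect:
    """Column layout of a per-trial CSV table.

    The default dialect is a frame counter column followed by the 9 channels
    in canonical order; files may omit trailing channel groups (acceleration
    only, or acceleration+gyro).  Alternative layouts are configured rather
    than hard-coded, since on-disk schemas vary between datasets.
    """

    frame_column: str | None = "frame"
    channel_columns: tuple[str, ...] = CHANNEL_NAMES
    delimiter: str = ","

    @classmethod
    def from_dict(cls, d: Mapping) -> "TableDialect":
        return cls(
            frame_column=d.get("frame_column", "frame"),
            channel_columns=tuple(d.get("channel_columns", CHANNEL_NAMES)),
            delimiter=d.get("delimiter", ","),
        )


DEFAULT_DIALECT = TableDialect()

_FILENAME_RE = re.compile(r"^(?P<subject>[^_]+)_(?P<task>.+)_T(?P<trial>\d+)$")


def trial_filename(subject_id: str, task_id: str, trial_id: int) -> str:
    return f"{subject_id}_{task_id}_T{int(trial_id):02d}.csv"


def read_trial_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    *,
    subject_id: str | None = None,
    task_id: str | None = None,
    trial_id: int | None = None,
    sample_rate_hz: float = 100.0,
) -> SensorTrace:
    """Read one trial table into a :class:`SensorTrace`.

    Identity metadata defaults to parsing the filename stem as
    ``{subject}_{task}_T{trial}``; pass the fields explicitly for other
    naming schemes.  Channel columns must form a prefix group (3, 6 or 9 of
    the dialect's channel columns, in order).
    """
    path = Path(path)
    try:
        # round_trip parsing so written traces re-read bit-identically
        frame = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    present = [c for c in dialect.channel_columns if c in frame.columns]
    if present != list(dialect.channel_columns[: len(present)]):
        missing = next(
            c for c in dialect.channel_columns if c not in frame.columns
        )
        raise FormatError(
            f"{path}: channel columns must be a contiguous prefix of "
            f"{dialect.channel_columns}; column {missing!r} is missing while "
            f"later ones are present"
        )
    if len(present) not in _VALID_CHANNEL_COUNTS:
        raise FormatError(
            f"{path}: found {len(present)} channel columns "
            f"({present}); expected 3, 6 or 9"
        )

    values = frame[present].to_numpy(dtype=float)
    if dialect.frame_column is not None and dialect.frame_column in frame.columns:
        counter = frame[dialect.frame_column].to_numpy()
        try:
            frame_index = counter.astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: frame column {dialect.frame_column!r} is not integer"
            ) from exc
        if len(frame_index) > 1 and not (np.diff(frame_index) == 1).all():
            raise DataError(f"{path}: frame counter has gaps or is non-monotone")
    else:
        frame_index = np.arange(len(values), dtype=np.int64)

    meta = _FILENAME_RE.match(path.stem)
    if subject_id is None:
        subject_id = meta.group("subject") if meta else path.stem
    if task_id is None:
        task_id = meta.group("task") if meta else "UNKNOWN"
    if trial_id is None:
        trial_id = int(meta.group("trial")) if meta else 1

    return SensorTrace(
        subject_id=subject_id,
        task_id=task_id,
        trial_id=trial_id,
        sample_rate_hz=sample_rate_hz,
        samples=values,
        frame_index=frame_index,
    )


def write_trial_table(
    trace: SensorTrace,
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> Path:
    """Write a trace in the given dialect (default: counter + channels).

    Synthetic and real trials share this path, so a written trace re-read with
    the same dialect reproduces all values exactly.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    if dialect.frame_column is not None:
        cols[dialect.frame_column] = trace.frame_index
    for i, name in enumerate(dialect.channel_columns[: trace.n_channels]):
        cols[name] = trace.samples[:, i]
    pd.DataFrame(cols).to_csv(path, sep=dialect.delimiter, index=False)
    return path


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

AnnotationKey = tuple  # (task_id, trial_id) or (subject_id, task_id, trial_id)


def read_annotation_table(path: str | Path) -> dict[AnnotationKey, FallAnnotation]:
    """Read a fall-annotation table.

    Expected columns: ``task_id, trial_id, onset_frame, impact_frame`` with an
    optional leading ``subject_id`` (keys then include the subject, which is
    required for multi-subject cohorts).  Rows with empty onset/impact cells
    (ADL rows) produce no entry.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"task_id", "trial_id", "onset_frame", "impact_frame"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    with_subject = "subject_id" in frame.columns

    out: dict[AnnotationKey, FallAnnotation] = {}
    for row in frame.itertuples(index=False):
        if pd.isna(row.onset_frame) or pd.isna(row.impact_frame):
            continue
        key: AnnotationKey = (
            (str(row.subject_id), str(row.task_id), int(row.trial_id))
            if with_subject
            else (str(row.task_id), int(row.trial_id))
        )
        try:
            out[key] = FallAnnotation(int(row.onset_frame), int(row.impact_frame))
        except DataError as exc:
            raise DataError(f"{path}: trial {key}: {exc}") from exc
    return out


def write_annotation_table(
    annotations: Mapping[AnnotationKey, FallAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for key, ann in annotations.items():
        if len(key) == 3:
            rows.append(
                {
                    "subject_id": key[0],
                    "task_id": key[1],
                    "trial_id": key[2],
                    "onset_frame": ann.onset_frame,
                    "impact_frame": ann.impact_frame,
                }
            )
        else:
            rows.append(
                {
                    "task_id": key[0],
                    "trial_id": key[1],
                    "onset_frame": ann.onset_frame,
                    "impact_frame": ann.impact_frame,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def lookup_annotation(
    annotations: Mapping[AnnotationKey, FallAnnotation], trace: SensorTrace
) -> FallAnnotation | None:
    """Find a trace's annotation under either key convention."""
    full = (trace.subject_id, trace.task_id, int(trace.trial_id))
    if full in annotations:
        return annotations[full]
    short = (trace.task_id, int(trace.trial_id))
    return annotations.get(short)
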