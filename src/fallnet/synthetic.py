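"""Synthetic annotated IMU cohorts: ADL trials and pre-impact fall trials.

The generator is phenomenological: piecewise kinematic templates plus noise,
carrying exactly the statistical structure the detection pipeline assumes —

* ADLs (static stance, sit/stand transitions, walking, jogging, bending):
  gravity-dominated acceleration with bounded, activity-specific dynamics and
  no impact-like spikes;
* falls: a prefall ADL segment, then a *fall phase* in which the acceleration
  magnitude ramps from ~1 g down to a free-fall floor with a direction-
  specific angular-velocity surge, an impact spike of several g, and a
  lying-still tail.  The onset/impact frame pair is returned as ground truth
  and is consistent with the generated signal by construction.

Channels follow the package convention (acc [g], gyro [deg/s], Euler [deg])
at 100 Hz.  Euler angles are synthesized directly from the orientation
template rather than integrated from the gyro channel, which avoids drift
bookkeeping at no cost to the pipeline (nothing downstream assumes the two
are consistent).  Per-subject amplitude/frequency offsets make subject-wise
splits meaningful.  Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    FallAnnotation,
    SensorTrace,
    write_annotation_table,
    write_trial_table,
    trial_filename,
)

ADL_KINDS = ("static", "sit_stand", "walk", "jog", "bend")
FALL_KINDS = ("forward", "backward", "lateral", "faint")

#: synthetic task codes; fall codes start with "F" like the KFall convention
ADL_CODES = {k: f"D_{k.upper()}" for k in ADL_KINDS}
FALL_CODES = {k: f"F_{k.upper()}" for k in FALL_KINDS}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults target a small but statistically meaningful cohort: 8 subjects ×
    (5 ADL + 4 fall kinds) × 2 trials = 144 trials, fall dynamics in the
    ranges typical of backward/forward falls in young adults (descent of
    300–700 ms, impact peaks of 3–8 g, free-fall magnitude floor 0.3 g).
    """

    n_subjects: int = 8
    trials_per_task: int = 2
    adl_kinds: tuple[str, ...] = ADL_KINDS
    fall_kinds: tuple[str, ...] = FALL_KINDS
    sample_rate_hz: float = 100.0
    adl_duration_s: tuple[float, float] = (5.0, 7.0)
    prefall_duration_s: tuple[float, float] = (2.5, 3.5)
    fall_duration_ms: tuple[float, float] = (300.0, 700.0)
    impact_peak_g: tuple[float, float] = (3.0, 8.0)
    prefall_freefall_floor_g: float = 0.3
    noise_sd_g: float = 0.03
    elderly_like: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("adl_duration_s", "prefall_duration_s", "fall_duration_ms",
                     "impact_peak_g"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ConfigError(f"{name} range must be positive and ordered")
        if not 0 < self.fall_duration_ms[1] <= 2000:
            raise ConfigError("fall durations must lie in (0, 2000] ms")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        unknown = set(self.adl_kinds) - set(ADL_KINDS)
        unknown |= set(self.fall_kinds) - set(FALL_KINDS)
        if unknown:
            raise ConfigError(f"unknown task kinds: {sorted(unknown)}")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject kinematic offsets (sampled once per subject)."""

    amp_scale: float = 1.0
    freq_scale: float = 1.0
    sway_g: float = 0.0  # extra low-frequency sway ("unbalanced movement")

    @classmethod
    def sample(cls, rng: np.random.Generator, elderly_like: bool) -> "SubjectProfile":
        return cls(
            amp_scale=float(rng.uniform(0.85, 1.15)),
            freq_scale=float(rng.uniform(0.9, 1.1)),
            sway_g=float(rng.uniform(0.08, 0.18)) if elderly_like else 0.0,
        )


@dataclass(frozen=True)
class SyntheticTrial:
    """A generated trace with its annotation (falls) and ground truth."""

    trace: SensorTrace
    annotation: FallAnnotation | None
    params: dict


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def _noise(rng, n, sd) -> np.ndarray:
    return rng.normal(0.0, sd, size=n)


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth 0→1→0 bump of length n."""
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def _adl_channels(
    kind: str, n: int, fs: float, rng: np.random.Generator,
    noise_sd: float, profile: SubjectProfile,
) -> np.ndarray:
    """9-channel ADL signal; acceleration magnitude stays well below 3 g."""
    t = np.arange(n) / fs
    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))
    euler = np.zeros((n, 3))
    a = profile.amp_scale

    if kind == "static":
        acc[:, 2] = 1.0
        gyr += rng.normal(0, 1.5, size=(n, 3))
        euler += rng.normal(0, 0.3, size=(n, 3))
    elif kind in ("walk", "jog"):
        if kind == "walk":
            f = rng.uniform(1.8, 2.2) * profile.freq_scale
            az, axy, gamp = rng.uniform(0.22, 0.32), rng.uniform(0.06, 0.12), rng.uniform(15, 35)
        else:
            f = rng.uniform(2.5, 3.2) * profile.freq_scale
            az, axy, gamp = rng.uniform(0.40, 0.55), rng.uniform(0.10, 0.18), rng.uniform(40, 80)
        phase = rng.uniform(0, 2 * np.pi, size=4)
        acc[:, 2] = 1.0 + a * az * np.sin(2 * np.pi * f * t + phase[0])
        acc[:, 0] = a * axy * np.sin(2 * np.pi * f * t + phase[1])
        acc[:, 1] = a * axy * np.sin(2 * np.pi * f / 2 * t + phase[2])
        gyr[:, 0] = a * gamp * np.sin(2 * np.pi * f * t + phase[3])
        gyr[:, 2] = 0.5 * a * gamp * np.sin(2 * np.pi * f / 2 * t + phase[1])
        euler[:, 1] = 4.0 * np.sin(2 * np.pi * f / 2 * t + phase[2])
    elif kind in ("sit_stand", "bend"):
        peak_angle = rng.uniform(35, 50) if kind == "sit_stand" else rng.uniform(55, 75)
        slow = 1.6 if profile.sway_g else 1.0  # unbalanced movers transition slower
        width = min(n, int(fs * rng.uniform(2.0, 3.0) * slow))
        start = rng.integers(0, max(n - width, 1))
        bump = np.zeros(n)
        bump[start : start + width] = _raised_cosine(width)
        acc[:, 2] = 1.0 + a * rng.uniform(0.15, 0.25) * np.gradient(bump) * fs / 4.0
        acc[:, 2] = np.clip(acc[:, 2], 0.55, 2.2)
        acc[:, 0] = a * 0.10 * bump
        gyr[:, 1] = a * rng.uniform(20, 45) * np.gradient(bump) * fs / 4.0
        euler[:, 1] = peak_angle * bump
    else:
        raise ConfigError(f"unknown ADL kind {kind!r}")

    if profile.sway_g:
        fsway = rng.uniform(0.3, 0.6)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        acc[:, 0] += profile.sway_g * np.sin(2 * np.pi * fsway * t + ph[0])
        acc[:, 2] += profile.sway_g * np.sin(2 * np.pi * fsway * t + ph[1])
        gyr[:, 1] += 20 * profile.sway_g * np.sin(2 * np.pi * fsway * t + ph[0])

    acc += rng.normal(0, noise_sd, size=(n, 3))
    gyr += rng.normal(0, 1.0, size=(n, 3))
    euler += rng.normal(0, 0.2, size=(n, 3))
    return np.hstack([acc, gyr, euler])


def simulate_adl(
    kind: str,
    duration_s: float = 6.0,
    seed: int = 0,
    cfg: SimConfig | None = None,
    profile: SubjectProfile | None = None,
    subject_id: str = "SYN01",
    trial_id: int = 1,
) -> SensorTrace:
    """One ADL trial of the given kind; deterministic per seed."""
    if duration_s < 1.0:
        raise ConfigError("ADL duration must be >= 1 s")
    if kind not in ADL_CODES:
        raise ConfigError(f"unknown ADL kind {kind!r}; expected one of {ADL_KINDS}")
    cfg = cfg or SimConfig()
    profile = profile or SubjectProfile()
    rng = _rng(seed)
    n = int(round(duration_s * cfg.sample_rate_hz))
    samples = _adl_channels(kind, n, cfg.sample_rate_hz, rng, cfg.noise_sd_g, profile)
    return SensorTrace(
        subject_id=subject_id,
        task_id=ADL_CODES[kind],
        trial_id=trial_id,
        sample_rate_hz=cfg.sample_rate_hz,
        samples=samples,
    )


_FALL_AXES = {
    # (tilt Euler channel, tilt sign, impact acc channel)
    "forward": (1, +1, 0),
    "backward": (1, -1, 0),
    "lateral": (0, +1, 1),
    "faint": (1, +1, 0),
}


def simulate_fall(
    prefall_kind: str = "walk",
    fall_kind: str = "forward",
    seed: int = 0,
    cfg: SimConfig | None = None,
    profile: SubjectProfile | None = None,
    subject_id: str = "SYN01",
    trial_id: int = 1,
) -> SyntheticTrial:
    """One annotated fall trial: prefall ADL → descent → impact → lying.

    During the annotated fall phase the acceleration magnitude ramps from
    ~1 g down to below the free-fall floor while the tilt axis surges; the
    impact frame opens a short spike whose peak equals the sampled
    ``impact_peak_g`` value exactly.
    """
    if fall_kind not in _FALL_AXES:
        raise ConfigError(f"unknown fall kind {fall_kind!r}; expected one of {FALL_KINDS}")
    cfg = cfg or SimConfig()
    profile = profile or SubjectProfile()
    rng = _rng(seed)
    fs = cfg.sample_rate_hz
    tilt_ch, tilt_sign, impact_ch = _FALL_AXES[fall_kind]

    # --- prefall ADL segment
    pre_s = rng.uniform(*cfg.prefall_duration_s)
    n_pre = int(round(pre_s * fs))
    pre = _adl_channels(prefall_kind, n_pre, fs, rng, cfg.noise_sd_g, profile)

    # --- descent (the annotated fall phase)
    duration_ms = float(rng.uniform(*cfg.fall_duration_ms))
    n_fall = max(2, int(round(duration_ms * fs / 1000.0)))
    tau = np.arange(n_fall) / (n_fall - 1)
    floor_end = cfg.prefall_freefall_floor_g * rng.uniform(0.4, 0.7)
    mag = floor_end + (1.0 - floor_end) * 0.5 * (1 + np.cos(np.pi * tau))
    theta = np.deg2rad(rng.uniform(55, 75)) * tau**1.5  # tilt angle ramp
    fall = np.zeros((n_fall, 9))
    fall[:, 2] = mag * np.cos(theta)
    fall[:, impact_ch] = tilt_sign * mag * np.sin(theta)
    fall[:, :3] += rng.normal(0, cfg.noise_sd_g * 0.5, size=(n_fall, 3))
    gyro_peak = tilt_sign * rng.uniform(90, 160)
    fall[:, 3 + tilt_ch] = gyro_peak * np.sin(np.pi * tau)
    fall[:, 3:6] += rng.normal(0, 2.0, size=(n_fall, 3))
    fall[:, 6 + tilt_ch] = tilt_sign * np.rad2deg(theta)
    fall[:, 6:9] += rng.normal(0, 0.3, size=(n_fall, 3))
    if fall_kind == "faint":  # slower, softer descent dynamics
        fall[:, 3 + tilt_ch] *= 0.6

    # --- impact spike (starts at the annotated impact frame)
    peak = float(rng.uniform(*cfg.impact_peak_g))
    shape = np.array([0.45, 1.0, 0.55, 0.30, 0.18, 0.10])
    n_imp = len(shape)
    imp = np.zeros((n_imp, 9))
    imp[:, impact_ch] = tilt_sign * peak * shape * 0.8
    imp[:, 2] = peak * shape * 0.6
    # normalize so the peak-frame magnitude equals the sampled peak exactly
    m = np.linalg.norm(imp[1, :3])
    imp[:, :3] *= peak / m
    imp[:, 3 + tilt_ch] = gyro_peak * np.array([0.8, 0.3, 0.1, 0.05, 0.0, 0.0])
    imp[:, 3:6] += rng.normal(0, 3.0, size=(n_imp, 3))
    imp[:, 6 + tilt_ch] = tilt_sign * rng.uniform(75, 88)

    # --- lying-still tail
    n_tail = int(round(rng.uniform(1.5, 2.5) * fs))
    tail = np.zeros((n_tail, 9))
    lie_angle = np.deg2rad(rng.uniform(75, 88))
    tail[:, impact_ch] = tilt_sign * np.sin(lie_angle)
    tail[:, 2] = np.cos(lie_angle)
    tail[:, :3] += rng.normal(0, cfg.noise_sd_g, size=(n_tail, 3))
    tail[:, 3:6] += rng.normal(0, 1.0, size=(n_tail, 3))
    tail[:, 6 + tilt_ch] = tilt_sign * np.rad2deg(lie_angle)
    tail[:, 6:9] += rng.normal(0, 0.2, size=(n_tail, 3))

    samples = np.vstack([pre, fall, imp, tail])
    trace = SensorTrace(
        subject_id=subject_id,
        task_id=FALL_CODES[fall_kind],
        trial_id=trial_id,
        sample_rate_hz=fs,
        samples=samples,
    )
    annotation = FallAnnotation(onset_frame=n_pre, impact_frame=n_pre + n_fall)
    return SyntheticTrial(
        trace=trace,
        annotation=annotation,
        params={
            "prefall_kind": prefall_kind,
            "fall_kind": fall_kind,
            "duration_ms": duration_ms,
            "impact_peak_g": peak,
            "onset_frame": n_pre,
            "impact_frame": n_pre + n_fall,
        },
    )


@dataclass
class Cohort:
    """Generated traces + annotations + per-trial manifest."""

    traces: list[SensorTrace]
    annotations: dict[tuple[str, str, int], FallAnnotation]
    manifest: pd.DataFrame
    config: SimConfig

    def subject_ids(self) -> list[str]:
        return sorted({t.subject_id for t in self.traces})


def generate_cohort(cfg: SimConfig = SimConfig()) -> Cohort:
    """A full cohort, deterministic given ``cfg.seed``.

    Every subject performs every configured ADL and fall kind
    ``trials_per_task`` times; fall trials draw their prefall activity from
    the walking/standing repertoire.  Child seeds are derived per
    (seed, subject, task, trial), so cohorts are reproducible and individual
    trials are independent of cohort size.
    """
    if cfg.n_subjects < 2:
        raise ConfigError("a cohort needs >= 2 subjects for subject-wise splits")
    traces: list[SensorTrace] = []
    annotations: dict[tuple[str, str, int], FallAnnotation] = {}
    rows = []
    prefall_cycle = ("walk", "static", "sit_stand")
    for s in range(1, cfg.n_subjects + 1):
        subject = f"SYN{s:02d}"
        profile = SubjectProfile.sample(_rng((cfg.seed, s, 0xA11)), cfg.elderly_like)
        for k, kind in enumerate(cfg.adl_kinds):
            for trial in range(1, cfg.trials_per_task + 1):
                trial_rng = _rng((cfg.seed, s, k, trial))
                duration = float(trial_rng.uniform(*cfg.adl_duration_s))
                trace = simulate_adl(
                    kind, duration, seed=(cfg.seed, s, k, trial, 1), cfg=cfg,
                    profile=profile, subject_id=subject, trial_id=trial,
                )
                traces.append(trace)
                rows.append(_manifest_row(trace, kind, None))
        for k, kind in enumerate(cfg.fall_kinds):
            for trial in range(1, cfg.trials_per_task + 1):
                prefall = prefall_cycle[(s + trial + k) % len(prefall_cycle)]
                sim = simulate_fall(
                    prefall, kind, seed=(cfg.seed, s, 100 + k, trial), cfg=cfg,
                    profile=profile, subject_id=subject, trial_id=trial,
                )
                traces.append(sim.trace)
                annotations[sim.trace.source] = sim.annotation
                rows.append(_manifest_row(sim.trace, kind, sim.annotation))
    manifest = pd.DataFrame(rows)
    return Cohort(traces=traces, annotations=annotations, manifest=manifest, config=cfg)


def _manifest_row(trace: SensorTrace, kind: str, ann: FallAnnotation | None) -> dict:
    return {
        "subject_id": trace.subject_id,
        "task_id": trace.task_id,
        "trial_id": trace.trial_id,
        "kind": kind,
        "n_frames": trace.n_frames,
        "onset_frame": None if ann is None else ann.onset_frame,
        "impact_frame": None if ann is None else ann.impact_frame,
    }


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write trials in the default table dialect + annotation and manifest
    tables, so synthetic and real data flow through one reader path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for trace in cohort.traces:
        write_trial_table(
            trace, directory / trial_filename(trace.subject_id, trace.task_id, trace.trial_id)
        )
    write_annotation_table(cohort.annotations, directory / "annotations.csv")
    cohort.manifest.to_csv(directory / "manifest.csv", index=False)
    return directory


def read_cohort(directory: str | Path) -> tuple[list[SensorTrace], dict]:
    """Read back a written cohort (trial tables + annotation table)."""
    from .io import read_annotation_table, read_trial_table

    directory = Path(directory)
    traces = [
        read_trial_table(p)
        for p in sorted(directory.glob("*.csv"))
        if p.name not in ("annotations.csv", "manifest.csv")
    ]
    ann_path = directory / "annotations.csv"
    annotations = read_annotation_table(ann_path) if ann_path.exists() else {}
    return traces, annotations
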