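"""Trial-level evaluation: confusion counts, rates, lead times, fraction tables.

Metrics are defined over whole trials ("files"), not windows:

* TP — fall trials where some window crossed the detection threshold;
* FN — fall trials where no window did;
* TN — ADL trials with every window below threshold;
* FP — ADL trials with at least one window misclassified as a fall.

Rates are percentages: sensitivity = TP/(TP+FN)·100, specificity =
TN/(FP+TN)·100, accuracy = (TP+TN)/(TP+FP+FN+TN)·100.  A zero denominator
yields ``None`` (reported NA), never 0.

The *lead time* of a detected fall is impact moment − detected moment — the
warning margin available to act (e.g. inflate a wearable airbag) before
ground contact.  Negative lead times (detection after impact) are kept and
flagged, not discarded.

Per-task × per-subject specificity *fraction tables* ("correct/total" cells,
NA where a subject skipped a task) are aggregated by summing numerators and
denominators over all non-NA cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .io import FallAnnotation


@dataclass(frozen=True)
class TrialPrediction:
    """One trial's window scores and first-crossing detection, if any."""

    source: tuple[str, str, int]
    window_scores: tuple[tuple[float, float], ...]  # (end_time_s, fall_prob)
    detected_moment_s: float | None
    is_fall_trial: bool

    def __post_init__(self) -> None:
        for _, p in self.window_scores:
            if not 0.0 <= p <= 1.0:
                raise DataError(f"probability {p} outside [0, 1]")

    @property
    def detected(self) -> bool:
        return self.detected_moment_s is not None


@dataclass
class MetricsReport:
    """Trial-level confusion counts, the three rates, and lead-time stats."""

    TP: int
    FP: int
    TN: int
    FN: int
    lead_times_ms: list[float] = field(default_factory=list)

    @property
    def n_fall_trials(self) -> int:
        return self.TP + self.FN

    @property
    def n_adl_trials(self) -> int:
        return self.TN + self.FP

    @property
    def sensitivity(self) -> float | None:
        d = self.TP + self.FN
        return 100.0 * self.TP / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.FP + self.TN
        return 100.0 * self.TN / d if d else None

    @property
    def accuracy(self) -> float | None:
        d = self.TP + self.FP + self.TN + self.FN
        return 100.0 * (self.TP + self.TN) / d if d else None

    @property
    def lead_time_mean_ms(self) -> float | None:
        return float(np.mean(self.lead_times_ms)) if self.lead_times_ms else None

    @property
    def lead_time_sd_ms(self) -> float | None:
        # population SD: a single lead time has spread 0, not NA
        return float(np.std(self.lead_times_ms)) if self.lead_times_ms else None

    def summary(self) -> str:
        def fmt(v: float | None) -> str:
            return "NA" if v is None else f"{v:.2f}"

        lines = [
            f"trials: {self.n_fall_trials} fall / {self.n_adl_trials} ADL",
            f"TP={self.TP} FP={self.FP} TN={self.TN} FN={self.FN}",
            f"sensitivity: {fmt(self.sensitivity)}%",
            f"specificity: {fmt(self.specificity)}%",
            f"accuracy:    {fmt(self.accuracy)}%",
        ]
        if self.lead_times_ms:
            lines.append(
                f"lead time:   {self.lead_time_mean_ms:.1f} "
                f"± {self.lead_time_sd_ms:.1f} ms (n={len(self.lead_times_ms)})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "lead_time_mean_ms": self.lead_time_mean_ms,
            "lead_time_sd_ms": self.lead_time_sd_ms,
            "n_lead_times": len(self.lead_times_ms),
        }


def compute_metrics(
    predictions: Sequence[TrialPrediction],
    annotations: Mapping | None = None,
    sample_rate_hz: float = 100.0,
) -> MetricsReport:
    """Confusion counts and rates over trial predictions.

    When ``annotations`` is given, lead times are collected for every detected
    fall trial with an annotation.
    """
    tp = fp = tn = fn = 0
    leads: list[float] = []
    for pred in predictions:
        if pred.is_fall_trial:
            if pred.detected:
                tp += 1
            else:
                fn += 1
        else:
            if pred.detected:
                fp += 1
            else:
                tn += 1
        if pred.is_fall_trial and annotations is not None:
            ann = _lookup(annotations, pred.source)
            if ann is not None:
                lead = compute_lead_time(pred, ann, sample_rate_hz)
                if lead is not None:
                    leads.append(lead)
    return MetricsReport(TP=tp, FP=fp, TN=tn, FN=fn, lead_times_ms=leads)


def _lookup(annotations: Mapping, source: tuple[str, str, int]):
    if source in annotations:
        return annotations[source]
    return annotations.get((source[1], source[2]))


def compute_lead_time(
    pred: TrialPrediction,
    annotation: FallAnnotation,
    sample_rate_hz: float = 100.0,
) -> float | None:
    """Lead time in ms: (impact moment − detected moment); None if undetected.

    Negative values mean the first threshold crossing came after impact; they
    are returned as-is so the caller can flag late detections.
    """
    if annotation is None:
        raise DataError(f"trial {pred.source} has no annotation for lead time")
    if not pred.detected:
        return None
    impact_s = annotation.impact_frame / sample_rate_hz
    return (impact_s - pred.detected_moment_s) * 1000.0


# ---------------------------------------------------------------------------
# fraction tables (per-task x per-subject specificity)
# ---------------------------------------------------------------------------

@dataclass
class FractionTable:
    """correct/total cells per (task, subject); missing cells are NA."""

    cells: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def add(self, task_id: str, subject_id: str, correct: int, total: int) -> None:
        if not 0 <= correct <= total:
            raise DataError(
                f"cell ({task_id}, {subject_id}): need 0 <= correct <= total, "
                f"got {correct}/{total}"
            )
        self.cells[(task_id, subject_id)] = (correct, total)

    def __len__(self) -> int:
        return len(self.cells)


def read_fraction_table(path: str | Path) -> FractionTable:
    """Read a task × subject table of ``a/b`` cells (``NA`` allowed).

    Layout: first column names the task; remaining column headers name the
    subjects — mirroring how per-movement/per-subject detection results are
    typically tabulated.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: need a task column plus subject columns")
    task_col = frame.columns[0]
    table = FractionTable()
    for _, row in frame.iterrows():
        for subject in frame.columns[1:]:
            cell = row[subject]
            if pd.isna(cell) or str(cell).strip().upper() in ("NA", ""):
                continue
            text = str(cell).strip()
            if "/" not in text:
                raise FormatError(
                    f"{path}: cell ({row[task_col]}, {subject}) is {text!r}; "
                    "expected 'correct/total' or NA"
                )
            num, den = text.split("/", 1)
            table.add(str(row[task_col]), str(subject), int(num), int(den))
    return table


def aggregate_fraction_table(table: FractionTable) -> tuple[float, int, int]:
    """Pooled specificity percent and (correct_sum, total_sum) over non-NA cells."""
    if not table.cells:
        raise DataError("fraction table has no non-NA cells")
    correct = sum(c for c, _ in table.cells.values())
    total = sum(t for _, t in table.cells.values())
    return round(100.0 * correct / total, 2), correct, total


def fraction_table_from_predictions(
    predictions: Sequence[TrialPrediction],
) -> FractionTable:
    """Build the per-task × per-subject table from ADL trial predictions.

    A trial counts as correct when no window crossed the threshold.
    """
    table = FractionTable()
    acc: dict[tuple[str, str], list[int]] = {}
    for pred in predictions:
        if pred.is_fall_trial:
            continue
        subject, task, _ = pred.source
        correct, total = acc.setdefault((task, subject), [0, 0])
        acc[(task, subject)][0] += 0 if pred.detected else 1
        acc[(task, subject)][1] += 1
    for (task, subject), (correct, total) in sorted(acc.items()):
        table.add(task, subject, correct, total)
    return table
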