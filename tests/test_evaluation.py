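"""Trial-level metrics, lead times, and fraction-table aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallnet import (
    FallAnnotation,
    TrialPrediction,
    aggregate_fraction_table,
    compute_lead_time,
    compute_metrics,
    fraction_table_from_predictions,
    read_fraction_table,
)
from fallnet.errors import DataError
from fallnet.evaluation import FractionTable
from fallnet.reference import reference_fraction_table


def make_pred(scores, is_fall, threshold=0.7, source=("S1", "F01", 1)):
    end_times = [0.49 + 0.1 * i for i in range(len(scores))]
    detected = next((t for t, p in zip(end_times, scores) if p >= threshold), None)
    return TrialPrediction(
        source=source,
        window_scores=tuple(zip(end_times, scores)),
        detected_moment_s=detected,
        is_fall_trial=is_fall,
    )


class TestComputeMetrics:
    def test_twelve_of_fifteen_falls_is_80_percent_sensitivity(self):
        preds = [make_pred([0.9], True) for _ in range(12)]
        preds += [make_pred([0.1], True) for _ in range(3)]
        report = compute_metrics(preds)
        assert report.TP == 12 and report.FN == 3
        assert report.sensitivity == pytest.approx(80.00)

    def test_627_clean_of_640_adl_is_9797_specificity(self):
        preds = [make_pred([0.1], False) for _ in range(627)]
        preds += [make_pred([0.95], False) for _ in range(13)]
        report = compute_metrics(preds)
        assert report.specificity == pytest.approx(97.97, abs=0.005)

    def test_perfect_two_trials(self):
        report = compute_metrics([make_pred([0.9], True), make_pred([0.1], False)])
        assert report.accuracy == pytest.approx(100.0)

    def test_undefined_rates_are_none_not_zero(self):
        only_adl = compute_metrics([make_pred([0.1], False)])
        assert only_adl.sensitivity is None
        assert only_adl.specificity == pytest.approx(100.0)
        only_fall = compute_metrics([make_pred([0.9], True)])
        assert only_fall.specificity is None

    @given(
        st.lists(
            st.tuples(
                st.booleans(),
                st.lists(st.floats(0, 1), min_size=1, max_size=6),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_against_enumeration_oracle(self, trials):
        preds = [make_pred(scores, is_fall) for is_fall, scores in trials]
        report = compute_metrics(preds)
        # oracle: a trial triggers iff ANY window score reaches threshold
        tp = sum(1 for f, s in trials if f and max(s) >= 0.7)
        fn = sum(1 for f, s in trials if f and max(s) < 0.7)
        fp = sum(1 for f, s in trials if not f and max(s) >= 0.7)
        tn = sum(1 for f, s in trials if not f and max(s) < 0.7)
        assert (report.TP, report.FN, report.FP, report.TN) == (tp, fn, fp, tn)
        total = tp + fn + fp + tn
        assert report.accuracy == pytest.approx(100.0 * (tp + tn) / total)
        for rate in (report.sensitivity, report.specificity, report.accuracy):
            assert rate is None or 0.0 <= rate <= 100.0

    @given(
        st.lists(st.lists(st.floats(0, 1), min_size=1, max_size=5),
                 min_size=1, max_size=20),
        st.floats(0.1, 0.9),
        st.floats(0.1, 0.9),
    )
    @settings(max_examples=60, derandomize=True)
    def test_threshold_monotonicity(self, score_sets, t_low, t_high):
        t_low, t_high = min(t_low, t_high), max(t_low, t_high)
        falls = [make_pred(s, True, threshold=t) for s in score_sets for t in ()]
        lo = compute_metrics([make_pred(s, True, t_low) for s in score_sets])
        hi = compute_metrics([make_pred(s, True, t_high) for s in score_sets])
        assert lo.TP >= hi.TP  # lowering the threshold never loses detections
        lo_adl = compute_metrics([make_pred(s, False, t_low) for s in score_sets])
        hi_adl = compute_metrics([make_pred(s, False, t_high) for s in score_sets])
        assert lo_adl.TN <= hi_adl.TN


class TestLeadTime:
    def test_arithmetic(self):
        pred = make_pred([0.9], True)
        pred = TrialPrediction(pred.source, pred.window_scores, 4.50, True)
        ann = FallAnnotation(onset_frame=450, impact_frame=500)
        assert compute_lead_time(pred, ann, 100.0) == pytest.approx(500.0)

    def test_undetected_is_none(self):
        pred = make_pred([0.1], True)
        assert compute_lead_time(pred, FallAnnotation(450, 500), 100.0) is None

    def test_detection_after_impact_is_negative(self):
        pred = TrialPrediction(("S1", "F01", 1), ((5.2, 0.9),), 5.2, True)
        assert compute_lead_time(pred, FallAnnotation(450, 500), 100.0) < 0

    def test_identical_leads_have_zero_sd(self):
        anns = {("F01", i): FallAnnotation(450, 500) for i in range(1, 4)}
        preds = [
            TrialPrediction(("S1", "F01", i), ((4.5, 0.9),), 4.5, True)
            for i in range(1, 4)
        ]
        report = compute_metrics(preds, anns)
        assert report.lead_time_mean_ms == pytest.approx(500.0)
        assert report.lead_time_sd_ms == pytest.approx(0.0)


class TestFractionTables:
    def test_single_cell(self):
        t = FractionTable()
        t.add("D01", "S1", 1, 1)
        assert aggregate_fraction_table(t) == (100.0, 1, 1)

    def test_all_na_is_error(self):
        with pytest.raises(DataError):
            aggregate_fraction_table(FractionTable())

    def test_correct_greater_than_total_rejected(self):
        with pytest.raises(DataError):
            FractionTable().add("D01", "S1", 6, 5)

    def test_read_table_with_na_cells(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("task,S1,S2\nD01,1/1,NA\nD02,3/5,5/5\n")
        table = read_fraction_table(p)
        assert len(table) == 3
        assert aggregate_fraction_table(table) == (pytest.approx(81.82), 9, 11)

    def test_malformed_cell_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("task,S1\nD01,five\n")
        with pytest.raises(Exception, match="five"):
            read_fraction_table(p)

    def test_bundled_single_window_table_pools_to_8781(self):
        pct, correct, total = aggregate_fraction_table(reference_fraction_table("single"))
        assert (correct, total) == (562, 640)
        assert pct == pytest.approx(87.81)

    def test_bundled_consecutive_table_pools_to_9797(self):
        pct, correct, total = aggregate_fraction_table(
            reference_fraction_table("consecutive")
        )
        assert (correct, total) == (627, 640)
        assert pct == pytest.approx(97.97)

    def test_table_from_predictions(self):
        preds = [
            make_pred([0.1], False, source=("S1", "D01", 1)),
            make_pred([0.9], False, source=("S1", "D01", 2)),
            make_pred([0.1], False, source=("S2", "D02", 1)),
            make_pred([0.9], True, source=("S1", "F01", 1)),  # ignored
        ]
        table = fraction_table_from_predictions(preds)
        assert table.cells[("D01", "S1")] == (1, 2)
        assert table.cells[("D02", "S2")] == (1, 1)
        assert ("F01", "S1") not in {k for k in table.cells}
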