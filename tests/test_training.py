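"""Training protocol: subject splits, early stopping, trial prediction."""

import numpy as np
import pytest

from fallnet import (
    TrainConfig,
    TrainedModel,
    predict_trial,
    split_subjects,
    train,
)
from fallnet.errors import ConfigError, DataError
from fallnet.windowing import FALL, NON_FALL, LabeledWindow, TrialWindows, WindowDataset


class TestSplitSubjects:
    def test_cohort_of_32_splits_26_6(self):
        ids = [f"S{i:02d}" for i in range(32)]
        train_ids, test_ids = split_subjects(ids, 0.8, seed=0)
        assert len(train_ids) == 26 and len(test_ids) == 6

    def test_same_seed_identical_split(self):
        ids = [f"S{i}" for i in range(10)]
        assert split_subjects(ids, 0.8, 5) == split_subjects(ids, 0.8, 5)

    def test_two_subjects_half(self):
        assert sorted(sum(split_subjects(["a", "b"], 0.5, 1), [])) == ["a", "b"]

    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_and_exhaustive(self, seed):
        ids = [f"S{i}" for i in range(13)]
        tr, te = split_subjects(ids, 0.8, seed)
        assert not set(tr) & set(te)
        assert sorted(tr + te) == sorted(ids)

    def test_bad_fraction(self):
        with pytest.raises(ConfigError):
            split_subjects(["a", "b"], 1.0, 0)


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ConfigError):
            TrainConfig(validation_fraction=0.0)
        with pytest.raises(ConfigError):
            TrainConfig(early_stop_patience=300)
        with pytest.raises(ConfigError):
            TrainConfig(softmax_threshold=1.0)


def _single_class_dataset(n=60):
    windows = tuple(
        LabeledWindow(("S1", "D01", 1), i, np.zeros((50, 6)), NON_FALL, 0.5 + i / 100)
        for i in range(n)
    )
    trial = TrialWindows(("S1", "D01", 1), windows, False, None, 100.0)
    return WindowDataset([trial])


class TestTrain:
    def test_single_class_data_rejected(self, tiny_spec):
        with pytest.raises(DataError, match="single class"):
            train(tiny_spec, _single_class_dataset(),
                  TrainConfig(seed=0, max_epochs=1, early_stop_patience=1))

    def test_shape_mismatch_rejected(self, tiny_spec, small_cohort):
        from fallnet import ChannelSelection, WindowingConfig, build_dataset

        ds9 = build_dataset(small_cohort.traces, small_cohort.annotations,
                            WindowingConfig(), ChannelSelection("imu9"))
        with pytest.raises(ConfigError, match="do not match"):
            train(tiny_spec, ds9, TrainConfig(seed=0, max_epochs=1, early_stop_patience=1))

    def test_flat_validation_stops_after_patience(self, tiny_spec, small_dataset):
        # zero learning rate => validation accuracy can never improve after
        # epoch 1, so training runs exactly patience + 1 epochs
        cfg = TrainConfig(seed=0, max_epochs=10, early_stop_patience=3,
                          learning_rate=0.0)
        model = train(tiny_spec, small_dataset, cfg)
        assert len(model.history.val_accuracy) == 4
        assert model.history.best_epoch == 0

    def test_seeded_training_reproducible(self, tiny_spec, small_dataset):
        cfg = TrainConfig(seed=11, max_epochs=2, early_stop_patience=2)
        h1 = train(tiny_spec, small_dataset, cfg).history
        h2 = train(tiny_spec, small_dataset, cfg).history
        assert h1.val_accuracy == h2.val_accuracy
        assert h1.train_loss == h2.train_loss

    def test_separable_cohort_reaches_high_validation_accuracy(self, tiny_model):
        assert max(tiny_model.history.val_accuracy) >= 0.95

    def test_best_weights_restored(self, tiny_model):
        # the restored network must reproduce the best recorded val accuracy
        assert tiny_model.history.best_epoch >= 0


class TestSaveLoad:
    def test_round_trip_preserves_predictions(self, tiny_model, small_dataset, tmp_path):
        x, _ = small_dataset.to_arrays()
        x = x[:8]
        before = tiny_model.fall_probability(x)
        tiny_model.save(tmp_path / "ckpt")
        loaded = TrainedModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(loaded.fall_probability(x), before)


class _StubModel:
    """Deterministic scores, for exercising the first-crossing rule."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def fall_probability(self, values):
        return self.scores[: len(values)]


def _trial_with_windows(end_times, label=NON_FALL, is_fall=False):
    windows = tuple(
        LabeledWindow(("S1", "F01" if is_fall else "D01", 1), int(t * 100) - 49,
                      np.zeros((50, 6)), label, t)
        for t in end_times
    )
    return TrialWindows(windows[0].source, windows, is_fall, None, 100.0)


class TestPredictTrial:
    def test_first_crossing_is_detected_moment(self):
        trial = _trial_with_windows([0.49, 0.59, 0.69], is_fall=True)
        pred = predict_trial(_StubModel([0.2, 0.71, 0.9]), trial, 0.7)
        assert pred.detected_moment_s == pytest.approx(0.59)

    def test_no_crossing_gives_none(self):
        trial = _trial_with_windows([0.49, 0.59])
        pred = predict_trial(_StubModel([0.3, 0.69]), trial, 0.7)
        assert pred.detected_moment_s is None

    def test_exact_threshold_ties_detect(self):
        trial = _trial_with_windows([0.49, 0.59])
        pred = predict_trial(_StubModel([0.7, 0.1]), trial, 0.7)
        assert pred.detected_moment_s == pytest.approx(0.49)

    def test_empty_trial_is_error(self):
        trial = TrialWindows(("S1", "D01", 1), (), False, None, 100.0)
        with pytest.raises(DataError):
            predict_trial(_StubModel([]), trial, 0.7)
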