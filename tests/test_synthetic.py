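"""Synthetic cohort generator: determinism, signal invariants, annotations."""

import numpy as np
import pytest

from fallnet import (
    FallAnnotation,
    SimConfig,
    WindowingConfig,
    generate_cohort,
    read_cohort,
    segment,
    simulate_adl,
    simulate_fall,
    write_cohort,
)
from fallnet.errors import ConfigError
from fallnet.windowing import FALL, label_window
from fallnet.synthetic import SubjectProfile


class TestSimulateAdl:
    def test_noise_free_static_magnitude_is_exactly_1g(self):
        trace = simulate_adl("static", 3.0, seed=0, cfg=SimConfig(noise_sd_g=0.0))
        np.testing.assert_allclose(trace.acc_magnitude(), 1.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_walk_magnitude_bounded(self, seed):
        trace = simulate_adl("walk", 4.0, seed=seed)
        mag = trace.acc_magnitude()
        assert 0.5 < mag.min() and mag.max() < 2.5

    def test_same_seed_identical_trace(self):
        a = simulate_adl("jog", 3.0, seed=5)
        b = simulate_adl("jog", 3.0, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_nine_channels_emitted(self):
        assert simulate_adl("bend", 2.0, seed=1).n_channels == 9

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError, match="cartwheel"):
            simulate_adl("cartwheel", 3.0, seed=0)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ConfigError):
            simulate_adl("walk", 0.5, seed=0)

    @pytest.mark.parametrize("kind", ["static", "sit_stand", "walk", "jog", "bend"])
    @pytest.mark.parametrize("seed", range(40))
    def test_adl_never_reaches_impact_magnitudes(self, kind, seed):
        cfg = SimConfig()
        trace = simulate_adl(kind, 4.0, seed=seed, cfg=cfg)
        assert trace.acc_magnitude().max() < cfg.impact_peak_g[0]

    def test_elderly_profile_adds_sway(self):
        calm = SubjectProfile(sway_g=0.0)
        swaying = SubjectProfile(sway_g=0.15)
        a = simulate_adl("static", 5.0, seed=2, profile=calm)
        b = simulate_adl("static", 5.0, seed=2, profile=swaying)
        assert b.samples[:, 0].std() > a.samples[:, 0].std() * 2


class TestSimulateFall:
    def test_500ms_fall_spans_50_frames(self):
        cfg = SimConfig(fall_duration_ms=(500.0, 500.0))
        sim = simulate_fall("walk", "forward", seed=3, cfg=cfg)
        assert sim.annotation.impact_frame - sim.annotation.onset_frame == 50

    @pytest.mark.parametrize("seed", range(50))
    def test_fall_phase_signal_invariants(self, seed):
        cfg = SimConfig()
        kind = ("forward", "backward", "lateral", "faint")[seed % 4]
        sim = simulate_fall("walk", kind, seed=seed, cfg=cfg)
        mag = sim.trace.acc_magnitude()
        onset, impact = sim.annotation.onset_frame, sim.annotation.impact_frame
        phase = mag[onset:impact]
        # descent: median below 1 g and the free-fall floor is reached
        assert np.median(phase) < 1.0
        assert phase.min() <= cfg.prefall_freefall_floor_g
        # impact: the configured minimum peak is exceeded at/after impact
        assert mag[impact : impact + 10].max() >= cfg.impact_peak_g[0]

    def test_fall_phase_produces_fall_windows(self):
        sim = simulate_fall("static", "backward", seed=9)
        cfg = WindowingConfig()
        windows = segment(sim.trace, cfg)
        labels = [label_window(w, sim.annotation, cfg) for w in windows]
        assert labels.count(FALL) >= 1

    def test_determinism(self):
        a = simulate_fall("sit_stand", "lateral", seed=4)
        b = simulate_fall("sit_stand", "lateral", seed=4)
        np.testing.assert_array_equal(a.trace.samples, b.trace.samples)
        assert a.annotation == b.annotation


class TestGenerateCohort:
    def test_identical_manifests_for_same_config(self):
        cfg = SimConfig(n_subjects=2, trials_per_task=1, seed=5)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.manifest.equals(b.manifest)
        np.testing.assert_array_equal(a.traces[0].samples, b.traces[0].samples)

    def test_every_subject_has_both_classes(self, small_cohort):
        by_subject = {}
        for trace in small_cohort.traces:
            by_subject.setdefault(trace.subject_id, set()).add(
                trace.task_id.startswith("F")
            )
        assert all(classes == {True, False} for classes in by_subject.values())

    def test_every_fall_trial_annotated(self, small_cohort):
        falls = [t for t in small_cohort.traces if t.task_id.startswith("F")]
        assert falls and all(t.source in small_cohort.annotations for t in falls)

    def test_single_subject_rejected(self):
        with pytest.raises(ConfigError):
            generate_cohort(SimConfig(n_subjects=1))

    def test_config_range_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(fall_duration_ms=(700.0, 300.0))
        with pytest.raises(ConfigError):
            SimConfig(adl_kinds=("static", "parkour"))

    def test_write_read_round_trip(self, tmp_path):
        cohort = generate_cohort(SimConfig(n_subjects=2, trials_per_task=1, seed=8))
        write_cohort(cohort, tmp_path / "cohort")
        traces, annotations = read_cohort(tmp_path / "cohort")
        assert len(traces) == len(cohort.traces)
        original = {t.source: t for t in cohort.traces}
        for trace in traces:
            np.testing.assert_array_equal(
                trace.samples, original[trace.source].samples
            )
        assert annotations == {
            key: FallAnnotation(ann.onset_frame, ann.impact_frame)
            for key, ann in cohort.annotations.items()
        }
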