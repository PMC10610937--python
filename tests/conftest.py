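"""Shared fixtures: small synthetic cohorts and a quickly trained model."""

from __future__ import annotations

import numpy as np
import pytest

from fallnet import (
    BlockSpec,
    ChannelSelection,
    ModelSpec,
    SimConfig,
    TrainConfig,
    WindowingConfig,
    build_dataset,
    generate_cohort,
    train,
)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x (5 ADL + 4 fall) x 1 trial = 36 annotated trials."""
    return generate_cohort(SimConfig(n_subjects=4, trials_per_task=1, seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return build_dataset(
        small_cohort.traces,
        small_cohort.annotations,
        WindowingConfig(),
        ChannelSelection("imu6"),
    )


@pytest.fixture(scope="session")
def tiny_spec():
    """A deliberately small conv net for fast training in tests."""
    return ModelSpec(
        family="vgg1d",
        input_channels=6,
        blocks=(
            BlockSpec("vgg_block", filters=8, kernel=3, with_bn=True),
            BlockSpec("max_pool", filters=1, kernel=1, with_bn=False, pool_size=2),
            BlockSpec("vgg_block", filters=16, kernel=3, with_bn=True),
        ),
        head="global_avg_pool_dense",
        name="tiny_conv",
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_spec, small_dataset):
    """A model trained for a handful of epochs on the small cohort."""
    cfg = TrainConfig(seed=3, max_epochs=6, early_stop_patience=6)
    return train(tiny_spec, small_dataset, cfg)
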