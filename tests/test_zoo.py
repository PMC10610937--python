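"""Architecture specs: builders, closed-form counts, and the lightweighting ladder."""

import pytest

from fallnet import (
    build_conv_lstm,
    build_resnet50_1d,
    build_tinyfallnet,
    build_vgg1d,
    count_parameters,
    derive_resnet24_from_vgg19,
    estimate_memory_mb,
    get_model_spec,
    lighten,
    list_models,
    slim_entry_conv_block,
)
from fallnet.errors import ConfigError
from fallnet.zoo import (
    IDENTITY_BLOCK,
    CONVOLUTIONAL_BLOCK,
    LSTM_UNIT,
    VGG_BLOCK,
    ModelSpec,
    count_conv_layers,
    load_spec_yaml,
    propagate_shapes,
    shipped_config_path,
    _conv_params,
    _dense_params,
    _lstm_params,
)

LADDER = ["resnet24", "resnet21", "resnet18", "resnet15", "resnet14"]


class TestClosedForms:
    @pytest.mark.parametrize(
        "fn,args,expected",
        [
            (_conv_params, (6, 7, 64), 2752),
            (_conv_params, (9, 7, 64), 4096),
            (_lstm_params, (64, 64), 33024),
            (_dense_params, (64, 2), 130),
        ],
    )
    def test_layer_formulas(self, fn, args, expected):
        assert fn(*args) == expected

    def test_running_stats_counted_separately(self):
        spec = get_model_spec("conv_lstm_9axis")
        n_bn_channels = 3 * 64  # three batch-normed conv units
        assert (
            count_parameters(spec, include_running_stats=True)
            - count_parameters(spec)
            == 2 * n_bn_channels
        )


class TestConvLstm:
    def test_benchmark_structure(self):
        spec = build_conv_lstm(9)
        kinds = [b.kind for b in spec.blocks]
        assert kinds == ["conv_unit"] * 3 + [LSTM_UNIT] * 2
        assert all(b.filters == 64 for b in spec.blocks)
        assert all(b.kernel == 7 for b in spec.blocks[:3])

    def test_six_axis_variant_same_blocks(self):
        a, b = build_conv_lstm(9), build_conv_lstm(6)
        assert a.blocks == b.blocks
        assert b.input_channels == 6

    def test_kernel3_variant_is_deeper(self):
        spec = build_conv_lstm(6, kernel=3, n_conv_units=4)
        assert sum(b.kind == "conv_unit" for b in spec.blocks) == 4
        assert all(b.kernel == 3 for b in spec.blocks[:4])


class TestVgg:
    def test_plain_vgg16_channel_doubling(self):
        spec = build_vgg1d(16)
        widths = [b.filters for b in spec.blocks if b.kind == VGG_BLOCK]
        assert widths == [64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512]
        assert not any(b.with_bn for b in spec.blocks if b.kind == VGG_BLOCK)

    def test_filters_override_uniform(self):
        spec = build_vgg1d(16, True, True, 64)
        assert all(b.filters == 64 for b in spec.blocks if b.kind == VGG_BLOCK)
        assert sum(b.kind == LSTM_UNIT for b in spec.blocks) == 2

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            build_vgg1d(17)
        with pytest.raises(ConfigError):
            build_vgg1d(16, filters_override=0)


class TestResnet:
    def test_scale_halves_filters(self):
        full = build_resnet50_1d(1.0)
        half = build_resnet50_1d(0.5)
        f_full = [b.filters for b in full.blocks if b.kind == CONVOLUTIONAL_BLOCK]
        f_half = [b.filters for b in half.blocks if b.kind == CONVOLUTIONAL_BLOCK]
        assert all(h == (f[0] // 2, f[1] // 2, f[2] // 2) for f, h in zip(f_full, f_half))

    def test_uniform_filters_64(self):
        spec = build_resnet50_1d(uniform_filters=64)
        triples = {b.filters for b in spec.blocks
                   if b.kind in (CONVOLUTIONAL_BLOCK, IDENTITY_BLOCK)}
        assert triples == {(16, 16, 64)}

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigError):
            build_resnet50_1d(0.0)


class TestResnet24Derivation:
    def test_half_as_many_residual_blocks_as_vgg19_convs(self):
        vgg19 = build_vgg1d(19, True, True, 64)
        n_convs = sum(b.kind == VGG_BLOCK for b in vgg19.blocks)
        resnet24 = derive_resnet24_from_vgg19()
        n_res = sum(
            b.kind in (IDENTITY_BLOCK, CONVOLUTIONAL_BLOCK) for b in resnet24.blocks
        )
        assert n_convs == 16 and n_res == n_convs // 2

    def test_fewer_parameters_than_vgg19(self):
        assert count_parameters(derive_resnet24_from_vgg19()) < count_parameters(
            build_vgg1d(19, True, True, 64)
        )

    def test_bottleneck_expand_is_4x_reduce(self):
        for b in derive_resnet24_from_vgg19().blocks:
            r, _, e = b.filters
            assert e == 4 * r

    def test_conv_layer_count_is_24(self):
        assert count_conv_layers(derive_resnet24_from_vgg19()) == 24


class TestLightweightingLadder:
    def test_lighten_zero_is_identity(self):
        spec = derive_resnet24_from_vgg19()
        assert lighten(spec, 0) == spec

    def test_ladder_names_track_conv_layers(self):
        for name, expected in zip(LADDER, (24, 21, 18, 15, 14)):
            assert count_conv_layers(get_model_spec(name)) == expected

    def test_lighten_preserves_all_stage_shapes(self):
        base = derive_resnet24_from_vgg19()
        light = lighten(base, 3)
        # shapes at every convolutional (stage-entry) block must agree
        base_shapes = [
            s for b, s in zip(base.blocks, propagate_shapes(base))
            if b.kind == CONVOLUTIONAL_BLOCK
        ]
        light_shapes = [
            s for b, s in zip(light.blocks, propagate_shapes(light))
            if b.kind == CONVOLUTIONAL_BLOCK
        ]
        assert base_shapes == light_shapes

    def test_parameters_strictly_decrease(self):
        params = [count_parameters(get_model_spec(n)) for n in LADDER]
        assert all(a > b for a, b in zip(params, params[1:]))

    def test_removing_too_many_identity_blocks(self):
        with pytest.raises(ConfigError):
            lighten(derive_resnet24_from_vgg19(), 4)

    def test_slim_step_keeps_shapes_and_sheds_parameters(self):
        r15 = get_model_spec("resnet15")
        r14 = slim_entry_conv_block(r15)
        assert propagate_shapes(r14) == propagate_shapes(r15)
        assert count_parameters(r14) < count_parameters(r15)
        assert count_conv_layers(r14) == 14


class TestMemoryEstimate:
    def test_mib_arithmetic(self):
        est = estimate_memory_mb(get_model_spec("tinyfallnet"))
        assert est.megabytes == pytest.approx(est.trainable_parameters * 4 / 1048576)

    def test_tinyfallnet_lighter_than_benchmark(self):
        tiny = estimate_memory_mb(get_model_spec("tinyfallnet")).megabytes
        bench = estimate_memory_mb(get_model_spec("conv_lstm_9axis")).megabytes
        assert tiny < bench

    def test_monotone_under_lighten(self):
        spec = derive_resnet24_from_vgg19()
        mems = [estimate_memory_mb(lighten(spec, k)).megabytes for k in range(4)]
        assert all(a > b for a, b in zip(mems, mems[1:]))


class TestSpecsAndConfigs:
    @pytest.mark.parametrize("name", list_models())
    def test_shape_propagation_all_variants(self, name):
        shapes = propagate_shapes(get_model_spec(name))
        assert all(length >= 1 for length, _ in shapes)

    @pytest.mark.parametrize("name", list_models())
    def test_shipped_yaml_matches_registry(self, name):
        assert load_spec_yaml(shipped_config_path(name)) == get_model_spec(name)

    def test_dict_round_trip(self):
        spec = build_tinyfallnet()
        assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_unknown_model_name(self):
        with pytest.raises(ConfigError, match="unknown model"):
            get_model_spec("resnet9000")
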