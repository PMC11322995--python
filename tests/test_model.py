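"""Architecture assembly: block shapes, residual behavior, seeding,
parameter accounting and the multi-branch fusion variants."""

import numpy as np
import pytest

from cropgcnn import (
    GCNNConfig,
    ImageBatch,
    build_gcnn,
    build_multibranch,
    expand_all,
    summarize,
)
from cropgcnn.model import (
    ConfigError,
    build_classification_block,
    build_processing_block,
    build_residual_block,
)
from cropgcnn.nn import BatchNorm2D, GroupedConv2D


def _zero_main_path(block):
    for layer in block.main.iter_layers():
        if isinstance(layer, GroupedConv2D):
            layer.W[...] = 0.0
            layer.b[...] = 0.0
        if isinstance(layer, BatchNorm2D):
            layer.beta[...] = 0.0


class TestBlocks:
    def test_processing_block_halves_space_and_sets_channels(self, rng):
        block = build_processing_block(GCNNConfig())
        out = block.forward(rng.random((2, 32, 32, 3)).astype(np.float32))
        assert out.shape == (2, 16, 16, 54)

    def test_processing_block_layer_order(self):
        names = [type(l).__name__ for l in build_processing_block(GCNNConfig()).iter_layers()]
        assert names == ["GroupedConv2D", "ReLU", "BatchNorm2D", "PReLU", "AvgPool2D"]

    def test_processing_block_lead_relu_ablation(self):
        names = [
            type(l).__name__
            for l in build_processing_block(GCNNConfig(lead_relu=False)).iter_layers()
        ]
        assert names == ["GroupedConv2D", "BatchNorm2D", "PReLU", "AvgPool2D"]

    def test_stem_conv_has_540_parameters(self):
        conv = next(iter(build_processing_block(GCNNConfig()).iter_layers()))
        assert conv.param_count() == 540

    def test_first_residual_block_projects_54_to_108(self, rng):
        block = build_residual_block(GCNNConfig(), 54)
        assert block.projection is not None
        out = block.forward(rng.random((1, 16, 16, 54)).astype(np.float32))
        assert out.shape == (1, 16, 16, 108)

    def test_residual_main_conv_has_17604_parameters(self):
        block = build_residual_block(GCNNConfig(), 54)
        conv = next(iter(block.main.iter_layers()))
        assert conv.param_count() == 17_604

    def test_zeroed_main_path_makes_identity_block(self, rng):
        """With matching channels a null residual leaves the input intact."""
        block = build_residual_block(GCNNConfig(), 108)
        assert block.projection is None
        _zero_main_path(block)
        x = rng.random((2, 8, 8, 108)).astype(np.float32)
        assert np.array_equal(block.forward(x), x)

    def test_skip_off_removes_shortcut(self, rng):
        block = build_residual_block(GCNNConfig(skip_mode="off"), 108)
        _zero_main_path(block)
        x = rng.random((1, 8, 8, 108)).astype(np.float32)
        assert np.allclose(block.forward(x), 0.0)

    def test_classification_block_flattens_to_6912(self):
        model = build_gcnn(GCNNConfig())
        flat_rows = [r for r in summarize(model).rows if r[0] == "cls_flatten"]
        assert flat_rows[0][1] == (6912,)

    def test_classification_head_widths(self):
        block = build_classification_block(GCNNConfig())
        dense = [l for l in block.iter_layers() if type(l).__name__ == "Dense"]
        assert [d.out_features for d in dense] == [128, 64, 10]


class TestGCNN:
    def test_forward_returns_probability_rows(self, rng):
        model = build_gcnn()
        p = model.forward(rng.random((4, 32, 32, 3)).astype(np.float32))
        assert p.shape == (4, 10)
        assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-5

    def test_same_seed_same_initial_outputs(self, rng):
        x = rng.random((3, 32, 32, 3)).astype(np.float32)
        a = build_gcnn(GCNNConfig(seed=9)).forward(x)
        b = build_gcnn(GCNNConfig(seed=9)).forward(x)
        assert np.array_equal(a, b)

    def test_summary_total_equals_parameter_enumeration(self):
        model = build_gcnn()
        s = summarize(model)
        assert s.total_params == sum(r[2] for r in s.rows)
        assert s.total_params == sum(p.size for p in model.params)

    def test_groups_one_triples_conv_weight_parameters(self):
        g3 = build_gcnn(GCNNConfig(groups=3))
        g1 = build_gcnn(GCNNConfig(groups=1))
        convs3 = [l for l in g3.layers if isinstance(l, GroupedConv2D)]
        convs1 = [l for l in g1.layers if isinstance(l, GroupedConv2D)]
        for a, b in zip(convs3, convs1):
            assert b.W.size == 3 * a.W.size
            assert b.b.size == a.b.size
        assert sum(p.size for p in g1.params) > sum(p.size for p in g3.params)

    def test_inference_forward_is_deterministic(self, rng):
        model = build_gcnn()
        x = rng.random((2, 32, 32, 3)).astype(np.float32)
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_save_load_roundtrip(self, tmp_path, rng):
        model = build_gcnn(GCNNConfig(seed=4))
        x = rng.random((2, 32, 32, 3)).astype(np.float32)
        model.save(tmp_path / "m.npz")
        from cropgcnn.model import GCNNModel

        again = GCNNModel.load(tmp_path / "m.npz")
        assert np.array_equal(model.forward(x), again.forward(x))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"groups": 4},                       # does not divide 54/108/3
            {"n_residual_blocks": 3},            # must be a multiple of 2
            {"n_residual_blocks": 0},
            {"dropout_rate": 1.0},
            {"skip_mode": "nearest"},
            {"input_size": (30, 30)},            # not divisible by 4
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GCNNConfig(**kwargs)


class TestMultiBranch:
    def test_concat_fusion_feature_width_is_7x64(self):
        model = build_multibranch()
        assert model.head.layers[0].in_features == 7 * 64 == 448

    def test_single_space_average_equals_plain_branch(self, rng):
        """Averaging one branch is that branch: outputs match the standalone
        GCNN fed the same converted, normalized input."""
        cfg = GCNNConfig(seed=21)
        mb = build_multibranch(cfg, spaces=("HSV",), fusion="average_probs")
        solo = build_gcnn(cfg)
        x = rng.random((3, 32, 32, 3))
        hsv = expand_all(ImageBatch(x))["HSV"].pixels.astype(np.float32)
        assert np.array_equal(mb.forward(x), solo.forward(hsv))

    @pytest.mark.parametrize("fusion", ["concat_features", "average_probs"])
    def test_output_rows_sum_to_one(self, fusion, rng):
        cfg = GCNNConfig(
            input_size=(16, 16), stage1_filters=6, stage2_filters=12,
            dense_units=(8, 4), n_classes=3, seed=0,
        )
        model = build_multibranch(cfg, spaces=("HSV", "LAB"), fusion=fusion)
        p = model.forward(rng.random((2, 16, 16, 3)))
        assert p.shape == (2, 3)
        assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-5

    def test_empty_and_duplicate_spaces_rejected(self):
        with pytest.raises(ConfigError):
            build_multibranch(spaces=())
        with pytest.raises(ConfigError):
            build_multibranch(spaces=("HSV", "HSV"))
        with pytest.raises(ConfigError):
            build_multibranch(spaces=("HSV", "CMYK"))

    def test_branch_grouped_layers_match_reference(self, rng):
        """Every grouped layer in a built branch satisfies the naive oracle."""
        from cropgcnn.gconv import ConvSpec, WeightSet, grouped_conv_forward

        cfg = GCNNConfig(
            input_size=(16, 16), stage1_filters=6, stage2_filters=12,
            dense_units=(8, 4), n_classes=3, seed=8,
        )
        model = build_gcnn(cfg)
        for layer in model.layers:
            if not isinstance(layer, GroupedConv2D):
                continue
            x = rng.normal(size=(1, 6, 6, layer.in_channels))
            spec = ConvSpec(
                layer.in_channels, layer.out_channels, layer.kernel,
                layer.groups, layer.padding, layer.use_bias,
            )
            ws = WeightSet(layer.W.astype(np.float64), layer.b.astype(np.float64))
            got = layer.forward(x.astype(np.float32))
            assert np.max(np.abs(got - grouped_conv_forward(x, spec, ws))) < 1e-5
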