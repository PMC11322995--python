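"""Grouped convolution: reference semantics, parameter accounting, and
equivalence between the naive reference and the vectorized trainable layer."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from cropgcnn.gconv import ConvSpec, SpecError, WeightSet, grouped_conv_forward, param_count
from cropgcnn.nn import GroupedConv2D

from _oracles import blockdiag_embed


def _random_case(rng, groups, in_c, out_c, kernel=(3, 3), padding="same",
                 bias=True, n=1, h=5, w=5):
    spec = ConvSpec(in_c, out_c, kernel, groups, padding, bias)
    ws = WeightSet.random(spec, rng)
    x = rng.normal(size=(n, h, w, in_c))
    return spec, ws, x


class TestReferenceSemantics:
    def test_groups_one_matches_scipy_full_convolution(self, rng):
        """With one group the layer is a plain multi-channel cross-correlation."""
        for padding in ("same", "valid"):
            spec, ws, x = _random_case(rng, 1, 4, 3, padding=padding)
            got = grouped_conv_forward(x, spec, ws)
            kh, kw = spec.kernel
            for oc in range(spec.out_channels):
                acc = sum(
                    correlate2d(x[0, :, :, ci], ws.weights[oc, ci],
                                mode=padding.replace("valid", "valid").replace("same", "same"))
                    for ci in range(spec.in_channels)
                ) + ws.bias[oc]
                assert np.allclose(got[0, :, :, oc], acc, atol=1e-10), (padding, oc)

    def test_grouped_equals_blockdiagonal_full(self, rng):
        """Grouped forward == full convolution with block-diagonal weights."""
        spec, ws, x = _random_case(rng, 2, 4, 6)
        full_spec = ConvSpec(4, 6, spec.kernel, 1, spec.padding, spec.bias)
        full_ws = WeightSet(blockdiag_embed(ws.weights, 2), ws.bias)
        a = grouped_conv_forward(x, spec, ws)
        b = grouped_conv_forward(x, full_spec, full_ws)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_one_by_one_identity_kernels_permute_channels(self):
        """1x1 kernels copying one in-channel per out-channel within a group."""
        spec = ConvSpec(4, 4, (1, 1), 2, "same", bias=False)
        w = np.zeros(spec.weight_shape)
        # within each group of 2 channels, swap the two channels
        for g in range(2):
            w[2 * g + 0, 1, 0, 0] = 1.0
            w[2 * g + 1, 0, 0, 0] = 1.0
        x = np.arange(2 * 3 * 3 * 4, dtype=float).reshape(2, 3, 3, 4)
        out = grouped_conv_forward(x, spec, WeightSet(w))
        assert np.array_equal(out, x[..., [1, 0, 3, 2]])

    def test_valid_padding_shrinks_by_kernel_minus_one(self, rng):
        spec, ws, x = _random_case(rng, 1, 2, 2, kernel=(3, 3), padding="valid", h=7, w=6)
        assert grouped_conv_forward(x, spec, ws).shape == (1, 5, 4, 2)

    def test_linearity_without_bias(self, rng):
        spec, ws, _ = _random_case(rng, 2, 4, 4, bias=False)
        x = rng.normal(size=(2, 5, 5, 4))
        y = rng.normal(size=(2, 5, 5, 4))
        lhs = grouped_conv_forward(2.0 * x - 3.0 * y, spec, ws)
        rhs = 2.0 * grouped_conv_forward(x, spec, ws) - 3.0 * grouped_conv_forward(y, spec, ws)
        assert np.max(np.abs(lhs - rhs)) < 1e-5

    def test_translation_equivariance_on_valid_padding(self, rng):
        spec, ws, _ = _random_case(rng, 2, 4, 4, padding="valid")
        x = rng.normal(size=(1, 9, 9, 4))
        shifted = np.roll(x, (2, 1), axis=(1, 2))
        a = grouped_conv_forward(x, spec, ws)
        b = grouped_conv_forward(shifted, spec, ws)
        # interior of the shifted output equals the shifted interior
        assert np.allclose(np.roll(a, (2, 1), axis=(1, 2))[:, 2:, 1:], b[:, 2:, 1:], atol=1e-10)

    def test_shape_and_spec_errors(self, rng):
        spec, ws, x = _random_case(rng, 2, 4, 4)
        with pytest.raises(SpecError):
            grouped_conv_forward(x[..., :3], spec, ws)
        with pytest.raises(SpecError):
            ConvSpec(4, 6, (3, 3), 4)
        with pytest.raises(SpecError):
            grouped_conv_forward(x, spec, WeightSet(ws.weights[:, :1], ws.bias))


class TestParamCount:
    @pytest.mark.parametrize(
        "in_c,out_c,groups,expected",
        [(3, 54, 3, 540), (54, 108, 3, 17_604)],
    )
    def test_main_layer_counts_by_enumeration(self, in_c, out_c, groups, expected, rng):
        """Counts equal direct enumeration of the constructed weight arrays."""
        spec = ConvSpec(in_c, out_c, (3, 3), groups)
        ws = WeightSet.random(spec, rng)
        enumerated = ws.weights.size + ws.bias.size
        assert param_count(spec) == enumerated == expected

    def test_weight_params_scale_inversely_with_groups(self):
        for groups in (1, 2, 3, 6):
            spec = ConvSpec(6, 12, (3, 3), groups, bias=False)
            assert param_count(spec) * groups == param_count(
                ConvSpec(6, 12, (3, 3), 1, bias=False)
            )

    def test_bias_unchanged_by_grouping(self):
        g1 = ConvSpec(6, 12, (3, 3), 1, bias=True)
        g3 = ConvSpec(6, 12, (3, 3), 3, bias=True)
        assert param_count(g1) - param_count(ConvSpec(6, 12, (3, 3), 1, bias=False)) == 12
        assert param_count(g3) - param_count(ConvSpec(6, 12, (3, 3), 3, bias=False)) == 12


class TestBackendEquivalence:
    def test_trainable_layer_matches_reference_on_random_cases(self, rng):
        """20 random (spec, input) cases: im2col layer == naive reference."""
        for _ in range(20):
            groups = int(rng.choice([1, 2, 3]))
            cg = int(rng.integers(1, 4))
            og = int(rng.integers(1, 4))
            kernel = (int(rng.integers(1, 4)), int(rng.integers(1, 4)))
            padding = str(rng.choice(["same", "valid"]))
            in_c, out_c = groups * cg, groups * og
            h = int(rng.integers(kernel[0], kernel[0] + 5))
            w = int(rng.integers(kernel[1], kernel[1] + 5))
            spec, ws, x = _random_case(
                rng, groups, in_c, out_c, kernel, padding, True, n=2, h=h, w=w
            )
            layer = GroupedConv2D(in_c, out_c, kernel, groups, padding, rng=rng)
            layer.W[...] = ws.weights
            layer.b[...] = ws.bias
            got = layer.forward(x.astype(np.float32))
            want = grouped_conv_forward(x, spec, ws)
            assert np.max(np.abs(got - want)) < 1e-5, (groups, kernel, padding)

    def test_trainable_layer_gradients_match_numerical(self, rng):
        layer = GroupedConv2D(4, 4, (3, 3), 2, "same", rng=rng)
        x = rng.normal(size=(2, 5, 5, 4)).astype(np.float32)
        dy = rng.normal(size=(2, 5, 5, 4)).astype(np.float32)
        out = layer.forward(x)
        dx = layer.backward(dy)
        loss = lambda: float((layer.forward(x) * dy).sum())
        eps = 1e-2
        gen = np.random.default_rng(0)
        for par, ana in [(layer.W, layer.dW), (layer.b, layer.db)]:
            flat, gflat = par.reshape(-1), ana.reshape(-1)
            for _ in range(5):
                j = gen.integers(flat.size)
                old = flat[j]
                flat[j] = old + eps
                lp = loss()
                flat[j] = old - eps
                lm = loss()
                flat[j] = old
                assert abs((lp - lm) / (2 * eps) - gflat[j]) < 5e-2 * max(
                    1.0, abs(gflat[j])
                )
        # input gradient via directional derivative
        v = rng.normal(size=x.shape).astype(np.float32)
        lp = float((layer.forward(x + eps * v) * dy).sum())
        lm = float((layer.forward(x - eps * v) * dy).sum())
        assert abs((lp - lm) / (2 * eps) - float((dx * v).sum())) < 1e-1
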