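from fractions import Fraction

import numpy as np
import pytest

from lesionseg import nn
from lesionseg.conv_math import (
    ConvSpec,
    InvalidSpecError,
    depthwise_conv_ref,
    dilated_conv_ref,
    effective_extent,
    param_ratio,
    pointwise_conv_ref,
    separable_conv_params,
    standard_conv_params,
)
from lesionseg.nn import Tensor


class TestParamCounts:
    def test_standard_small(self):
        spec = ConvSpec(kernel_size=3, in_channels=3, out_channels=16)
        assert standard_conv_params(spec).parameters == 432

    def test_standard_unity(self):
        spec = ConvSpec(kernel_size=1, in_channels=1, out_channels=1)
        assert standard_conv_params(spec).parameters == 1

    def test_standard_mult_adds(self):
        spec = ConvSpec(3, 3, 16, height=256, width=256)
        assert standard_conv_params(spec).mult_adds == 28_311_552

    def test_separable_small(self):
        spec = ConvSpec(kernel_size=3, in_channels=3, out_channels=16)
        assert separable_conv_params(spec).parameters == 75  # 27 depthwise + 48 pointwise

    def test_separable_unity(self):
        spec = ConvSpec(kernel_size=1, in_channels=1, out_channels=1)
        assert separable_conv_params(spec).parameters == 2

    def test_separable_mult_adds(self):
        spec = ConvSpec(3, 16, 32, height=64, width=64)
        assert separable_conv_params(spec).mult_adds == (144 + 512) * 4096

    @pytest.mark.parametrize("field", ["kernel_size", "in_channels", "out_channels"])
    def test_invalid_spec(self, field):
        kwargs = dict(kernel_size=3, in_channels=3, out_channels=16)
        kwargs[field] = 0
        with pytest.raises(InvalidSpecError):
            ConvSpec(**kwargs)

    def test_formula_matches_instantiated_layers(self, rng):
        # bias-free layer weight counts equal the closed forms, 10 random specs
        for _ in range(10):
            k = int(rng.choice([1, 3, 5]))
            M = int(rng.integers(1, 12))
            N = int(rng.integers(1, 12))
            spec = ConvSpec(k, M, N)
            std_layer = nn.Conv2d(M, N, k)
            assert std_layer.weight.data.size == standard_conv_params(spec).parameters
            dw = nn.DepthwiseConv2d(M, k)
            pw = nn.Conv2d(M, N, 1)
            sep_count = dw.weight.data.size + pw.weight.data.size
            assert sep_count == separable_conv_params(spec).parameters


class TestParamRatio:
    def test_large_n_approaches_nine(self):
        spec = ConvSpec(3, 1024, 1024)
        reciprocal = 1.0 / param_ratio(spec)
        assert 8.0 <= reciprocal <= 9.0
        assert reciprocal == pytest.approx(8.9216, abs=1e-3)

    def test_degenerate_has_more_parameters(self):
        assert param_ratio(ConvSpec(1, 1, 1)) == 2.0

    def test_k3_n16(self):
        assert param_ratio(ConvSpec(3, 5, 16)) == pytest.approx(
            1 / 16 + 1 / 9, abs=1e-9
        )
        assert param_ratio(ConvSpec(3, 5, 16)) == pytest.approx(0.173611, abs=1e-6)

    @pytest.mark.parametrize("n", [1, 2, 7, 16, 128, 10_000])
    def test_exact_integer_identity_k3(self, n):
        # standard/separable == 1 / (1/N + 1/9) exactly, and < 9 for finite N
        spec = ConvSpec(3, 4, n)
        std = standard_conv_params(spec).parameters
        sep = separable_conv_params(spec).parameters
        assert Fraction(std, sep) == 1 / (Fraction(1, n) + Fraction(1, 9))
        assert Fraction(std, sep) < 9


class TestDepthwiseRef:
    def test_identity_kernel(self, rng):
        image = rng.random((6, 6, 3))
        kern = np.zeros((3, 3, 3))
        kern[:, 1, 1] = 1.0
        np.testing.assert_allclose(depthwise_conv_ref(image, kern), image)

    def test_impulse_response(self):
        image = np.zeros((7, 7, 1))
        image[3, 3, 0] = 1.0
        out = depthwise_conv_ref(image, np.ones((1, 3, 3)))
        expected = np.zeros((7, 7))
        expected[2:5, 2:5] = 1.0
        np.testing.assert_allclose(out[..., 0], expected)

    def test_channel_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            depthwise_conv_ref(rng.random((4, 4, 3)), np.ones((2, 3, 3)))


class TestPointwiseRef:
    def test_identity(self, rng):
        image = rng.random((5, 5, 1))
        np.testing.assert_allclose(pointwise_conv_ref(image, [[1.0]]), image)

    def test_channel_sum(self, rng):
        image = rng.random((4, 4, 2))
        out = pointwise_conv_ref(image, [[1.0], [1.0]])
        np.testing.assert_allclose(out[..., 0], image.sum(-1))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            pointwise_conv_ref(rng.random((4, 4, 3)), np.ones((2, 4)))


class TestDilatedRef:
    def test_rate_one_equals_standard(self, rng):
        image = rng.random((8, 8, 2))
        kern = rng.normal(size=(3, 3))
        per_channel = np.stack([kern, kern])
        np.testing.assert_allclose(
            dilated_conv_ref(image, kern, rate=1),
            depthwise_conv_ref(image, per_channel),
        )

    def test_impulse_rate_two(self):
        image = np.zeros((9, 9, 1))
        image[4, 4, 0] = 1.0
        out = dilated_conv_ref(image, np.ones((3, 3)), rate=2)
        nz = np.argwhere(out[..., 0] == 1.0) - 4
        expected = {(i, j) for i in (-2, 0, 2) for j in (-2, 0, 2)}
        assert set(map(tuple, nz)) == expected
        assert out.sum() == 9

    def test_effective_extent(self):
        assert effective_extent(3, 2) == 5
        assert effective_extent(3, 1) == 3

    def test_extent_exceeds_input(self, rng):
        with pytest.raises(ValueError):
            dilated_conv_ref(rng.random((4, 4, 1)), np.ones((3, 3)), rate=4)


class TestOracleEquivalence:
    """Naive references vs the vectorized network layers, 20 seeded trials."""

    def test_depthwise_matches_fast_layer(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            image = r.normal(size=(8, 8, 4))
            kern = r.normal(size=(4, 3, 3))
            ref = depthwise_conv_ref(image, kern)
            fast = nn.depthwise_conv2d(
                Tensor(image.transpose(2, 0, 1)[None]), Tensor(kern)
            ).data[0].transpose(1, 2, 0)
            np.testing.assert_allclose(fast, ref, atol=1e-5)

    def test_pointwise_matches_fast_layer(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            image = r.normal(size=(8, 8, 4))
            weights = r.normal(size=(4, 6))
            ref = pointwise_conv_ref(image, weights)
            w = weights.T[:, :, None, None]  # (N, M, 1, 1)
            fast = nn.conv2d(
                Tensor(image.transpose(2, 0, 1)[None]), Tensor(w)
            ).data[0].transpose(1, 2, 0)
            np.testing.assert_allclose(fast, ref, atol=1e-5)

    def test_dilated_matches_fast_layer(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            image = r.normal(size=(8, 8, 1))
            kern = r.normal(size=(3, 3))
            ref = dilated_conv_ref(image, kern, rate=2)
            fast = nn.conv2d(
                Tensor(image.transpose(2, 0, 1)[None]),
                Tensor(kern[None, None]),
                dilation=2,
            ).data[0].transpose(1, 2, 0)
            np.testing.assert_allclose(fast, ref, atol=1e-5)

    def test_separable_composition_matches_fast_layers(self):
        # pointwise(depthwise(x)) by brute force == the DSC layer pair
        for seed in range(20):
            r = np.random.default_rng(seed)
            image = r.normal(size=(8, 8, 3))
            dw_k = r.normal(size=(3, 3, 3))
            pw_w = r.normal(size=(3, 5))
            ref = pointwise_conv_ref(depthwise_conv_ref(image, dw_k), pw_w)
            x = Tensor(image.transpose(2, 0, 1)[None])
            mid = nn.depthwise_conv2d(x, Tensor(dw_k))
            fast = nn.conv2d(
                mid, Tensor(pw_w.T[:, :, None, None])
            ).data[0].transpose(1, 2, 0)
            np.testing.assert_allclose(fast, ref, atol=1e-5)
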