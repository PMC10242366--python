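"""Structural and numerical checks of the network building blocks.

Parameter counts are compared against closed-form oracles (conv:
k*k*c_in*c_out + c_out; batch norm: 2 trainable per channel; PReLU: one
slope per channel). Deep-supervision graphs are compared against explicitly
hand-wired reference computations on tiny inputs.
"""

import numpy as np
import pytest

from spineseg import nn
from spineseg.blocks import (
    AttentionGate,
    DenseConvBlock,
    DSv1,
    DSv2,
    DSv3,
    MultiKernelInput,
    UNetConvBlock,
    VGGConvBlock,
)
from spineseg.nn import functional as F


def conv_params(k, cin, cout):
    return k * k * cin * cout + cout


class TestUNetConvBlock:
    def test_shape_contract(self, rng):
        block = UNetConvBlock(2, 8, rng)
        y = block(nn.Tensor(rng.normal(size=(1, 64, 64, 2))), training=True)
        assert y.shape == (1, 64, 64, 8)
        assert np.isfinite(y.data).all()

    def test_parameter_count_closed_form(self, rng):
        block = UNetConvBlock(2, 8, rng)
        # two 3x3 convs (2->8, 8->8) + two BNs of 8 channels
        expected = conv_params(3, 2, 8) + conv_params(3, 8, 8) + 2 * (2 * 8)
        assert block.parameter_count() == expected == 768

    def test_rejects_zero_channels(self, rng):
        with pytest.raises(ValueError):
            UNetConvBlock(2, 0, rng)


class TestVGGConvBlock:
    @pytest.mark.parametrize("depth", [2, 3])
    def test_shape_and_depth(self, rng, depth):
        block = VGGConvBlock(4, 6, depth, rng)
        y = block(nn.Tensor(rng.normal(size=(1, 32, 32, 4))))
        assert y.shape == (1, 32, 32, 6)
        assert len(block.convs) == depth

    def test_prelu_slopes_trainable_one_per_channel(self, rng):
        block = VGGConvBlock(4, 6, 2, rng)
        slopes = [p for name, p in block.named_parameters() if "alpha" in name]
        assert len(slopes) == 2
        assert all(s.data.shape == (6,) and s.requires_grad for s in slopes)

    def test_parameter_count_closed_form(self, rng):
        block = VGGConvBlock(4, 6, 3, rng)
        expected = (
            conv_params(3, 4, 6) + 2 * conv_params(3, 6, 6) + 3 * 6  # PReLU slopes
        )
        assert block.parameter_count() == expected

    def test_bad_depth_rejected(self, rng):
        with pytest.raises(ValueError):
            VGGConvBlock(4, 6, 4, rng)


class TestDenseConvBlock:
    def test_output_is_64_channels(self, rng):
        block = DenseConvBlock(2, rng)
        y = block(nn.Tensor(rng.normal(size=(1, 32, 32, 2))))
        assert y.shape == (1, 32, 32, 64)

    def test_dense_concat_widths(self, rng):
        assert DenseConvBlock(2, rng).unit_input_channels == (2, 66, 130)

    def test_stacking_keeps_64(self, rng):
        b1, b2 = DenseConvBlock(2, rng), DenseConvBlock(64, rng)
        y = b2(b1(nn.Tensor(rng.normal(size=(1, 16, 16, 2)))))
        assert y.shape == (1, 16, 16, 64)

    def test_parameter_count_closed_form(self, rng):
        block = DenseConvBlock(2, rng)
        expected = (
            conv_params(5, 2, 64) + conv_params(3, 66, 64) + conv_params(1, 130, 64)
            + 2 * (2 + 66 + 130)  # batch norms
        )
        assert block.parameter_count() == expected


class TestMultiKernelInput:
    def test_concat_width_is_m(self, rng):
        mk = MultiKernelInput(2, 64, rng)
        y = mk(nn.Tensor(rng.normal(size=(1, 64, 64, 2))))
        assert y.shape == (1, 64, 64, 64)

    def test_kernel_sizes_are_1357(self, rng):
        mk = MultiKernelInput(2, 16, rng)
        assert [p.weight.data.shape[0] for p in mk.paths] == [1, 3, 5, 7]

    def test_zero_input_zero_bias_gives_zero(self, rng):
        mk = MultiKernelInput(2, 16, rng)
        y = mk(nn.Tensor(np.zeros((1, 16, 16, 2))))
        assert (y.data == 0).all()

    def test_m_not_divisible_by_4_rejected(self, rng):
        with pytest.raises(ValueError):
            MultiKernelInput(2, 6, rng)


class TestAttentionGate:
    def make(self, rng, ce=8, cg=16):
        return AttentionGate(ce, cg, rng)

    def test_identity_gate_when_mask_forced_to_one(self, rng):
        ag = self.make(rng)
        ag.psi.weight.data[:] = 0.0
        ag.psi.bias.data[:] = 50.0  # sigmoid saturates at 1
        enc = nn.Tensor(rng.normal(size=(1, 8, 8, 8)))
        gate = nn.Tensor(rng.normal(size=(1, 4, 4, 16)))
        np.testing.assert_allclose(ag(enc, gate).data, enc.data, atol=1e-6)

    def test_zero_gate_when_mask_forced_to_zero(self, rng):
        ag = self.make(rng)
        ag.psi.weight.data[:] = 0.0
        ag.psi.bias.data[:] = -50.0
        enc = nn.Tensor(rng.normal(size=(1, 8, 8, 8)))
        gate = nn.Tensor(rng.normal(size=(1, 4, 4, 16)))
        assert np.abs(ag(enc, gate).data).max() < 1e-6

    def test_gating_attenuates(self, rng):
        ag = self.make(rng)
        enc = nn.Tensor(rng.normal(size=(2, 8, 8, 8)))
        gate = nn.Tensor(rng.normal(size=(2, 4, 4, 16)))
        out = ag(enc, gate).data
        assert (np.abs(out) <= np.abs(enc.data) + 1e-12).all()

    def test_mismatched_extent_rejected(self, rng):
        ag = self.make(rng)
        with pytest.raises(ValueError):
            ag(nn.Tensor(rng.normal(size=(1, 8, 8, 8))),
               nn.Tensor(rng.normal(size=(1, 3, 3, 16))))


def _enc_stack(rng, extent, channels, levels):
    """Random encoder outputs with halving extents."""
    return [
        nn.Tensor(rng.normal(size=(1, extent // 2**n, extent // 2**n, channels[n])))
        for n in range(levels)
    ]


def _conv1x1(conv, x):
    return x @ conv.weight.data[0, 0] + conv.bias.data


def _up(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _pool_max(x):
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


class TestDeepSupervision:
    def test_dsv1_extent_schedule(self, rng):
        C = _enc_stack(rng, 64, [4, 8, 16, 32, 64], 5)
        S = DSv1([4, 8, 16, 32, 64], 8, rng)(C)
        assert [s.shape[1] for s in S] == [64, 32, 16, 8, 4]
        assert all(s.shape[3] == 8 for s in S)

    def test_dsv1_zero_convs_give_zero_signals(self, rng):
        ds = DSv1([4, 8], 4, rng)
        for conv in ds.convs:
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        C = _enc_stack(rng, 16, [4, 8], 2)
        assert all((s.data == 0).all() for s in ds(C))

    def test_dsv1_matches_hand_wired_two_level_graph(self, rng):
        ds = DSv1([4, 8], 4, rng)
        C = _enc_stack(rng, 16, [4, 8], 2)
        S = ds(C)
        s2 = _conv1x1(ds.convs[1], C[1].data)
        s1 = _conv1x1(ds.convs[0], C[0].data) + _up(s2)
        np.testing.assert_allclose(S[1].data, s2, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(S[0].data, s1, rtol=1e-5, atol=1e-6)

    def test_dsv2_matches_hand_wired_three_level_graph(self, rng):
        ds = DSv2([4, 8, 16], 4, rng)
        C = _enc_stack(rng, 16, [4, 8, 16], 3)
        S = ds(C)
        prev3 = _conv1x1(ds.convs[2], C[2].data)
        prev2 = _conv1x1(ds.convs[1], C[1].data) + _up(prev3)
        prev1 = _conv1x1(ds.convs[0], C[0].data) + _up(prev2)
        s1 = prev1
        s2 = prev2 + _pool_max(s1)
        s3 = prev3 + _pool_max(s2)
        for got, want in zip(S, (s1, s2, s3)):
            np.testing.assert_allclose(got.data, want, rtol=1e-5, atol=1e-6)

    def test_dsv2_prevs_extents_match_s_extents(self, rng):
        ds = DSv2([4, 8, 16], 4, rng)
        C = _enc_stack(rng, 64, [4, 8, 16], 3)
        S = ds(C)
        assert [s.shape[1] for s in S] == [64, 32, 16]

    def test_dsv3_base_case_single_level(self, rng):
        ds = DSv3([8], 4, rng)
        T = [nn.Tensor(rng.normal(size=(1, 8, 8, 8)))]
        np.testing.assert_allclose(
            ds(T).data, _conv1x1(ds.convs[0], T[0].data), rtol=1e-5, atol=1e-6
        )

    def test_dsv3_matches_hand_wired_recursion(self, rng):
        ds = DSv3([4, 8, 16], 4, rng)
        T = _enc_stack(rng, 16, [4, 8, 16], 3)
        z3 = _conv1x1(ds.convs[2], T[2].data)
        z2 = _conv1x1(ds.convs[1], T[1].data) + _up(z3)
        z1 = _conv1x1(ds.convs[0], T[0].data) + _up(z2)
        np.testing.assert_allclose(ds(T).data, z1, rtol=1e-5, atol=1e-6)

    def test_dsv3_zero_convs_give_zero(self, rng):
        ds = DSv3([4, 8], 4, rng)
        for conv in ds.convs:
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        T = _enc_stack(rng, 8, [4, 8], 2)
        assert (ds(T).data == 0).all()

    @pytest.mark.parametrize("cls", [DSv1, DSv2])
    def test_homogeneity_doubling_weights_doubles_signals(self, rng, cls):
        channels = [4, 8, 16]
        ds = cls(channels, 4, rng)
        for conv in ds.convs:
            conv.bias.data[:] = 0
        C = _enc_stack(rng, 16, channels, 3)
        before = [s.data.copy() for s in ds(C)]
        for conv in ds.convs:
            conv.weight.data *= 2
        after = ds(C)
        for b, a in zip(before, after):
            np.testing.assert_allclose(a.data, 2 * b, rtol=1e-5, atol=1e-6)


class TestSpatialContracts:
    @pytest.mark.parametrize("extent", [16, 32, 48])
    def test_blocks_preserve_extent(self, rng, extent):
        x = nn.Tensor(rng.normal(size=(1, extent, extent, 4)))
        for block in (
            UNetConvBlock(4, 8, rng),
            VGGConvBlock(4, 8, 2, rng),
            DenseConvBlock(4, rng),
            MultiKernelInput(4, 8, rng),
        ):
            assert block(x).shape[1:3] == (extent, extent)

    def test_pool_halves_and_upsample_doubles(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 32, 32, 4)))
        assert F.max_pool2x2(x).shape[1:3] == (16, 16)
        assert F.upsample_nearest2x(x).shape[1:3] == (64, 64)
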