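"""Interchangeable building blocks for the U-Net variants.

Three convolutional block types (original U-Net, VGG16-style, densely
connected), a multi-kernel input stage, a spatial attention gate, and the
three deep-supervision signal graphs (DS.v1/DS.v2 between the branches,
DS.v3 in front of the classification block).

Conventions fixed here (the source architectures leave them open):
upsampling inside deep-supervision paths and attention gates is nearest
neighbour x2; transposed convolutions use 2x2 kernels with stride 2; the
1x1 deep-supervision convolutions all have width ``m`` (the base channel
count); the attention gate's intermediate width is half the encoder feature
width; VGG blocks follow the VGG16 level depths (2, 2, 3, 3, 3).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F

VGG_LEVEL_DEPTH = {1: 2, 2: 2, 3: 3, 4: 3, 5: 3}
DENSE_CHANNELS = 64


class _Activation(nn.Module):
    """ReLU or channel-wise PReLU, selected per topology."""

    def __init__(self, kind: str, channels: int):
        if kind not in ("relu", "prelu"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        if kind == "prelu":
            self.prelu = nn.PReLU(channels)

    def forward(self, x, training=False):
        return F.relu(x) if self.kind == "relu" else self.prelu(x)


class UNetConvBlock(nn.Module):
    """[conv 3x3 -> batch norm -> activation] twice (default ReLU)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, activation="relu"):
        if c_out < 1:
            raise ValueError("channels must be >= 1")
        self.conv1 = nn.Conv2D(c_in, c_out, 3, rng)
        self.bn1 = nn.BatchNorm2D(c_out)
        self.act1 = _Activation(activation, c_out)
        self.conv2 = nn.Conv2D(c_out, c_out, 3, rng)
        self.bn2 = nn.BatchNorm2D(c_out)
        self.act2 = _Activation(activation, c_out)
        self.out_channels = c_out

    def forward(self, x, training=False):
        x = self.act1(self.bn1(self.conv1(x), training))
        x = self.act2(self.bn2(self.conv2(x), training))
        return x


class VGGConvBlock(nn.Module):
    """Two or three 3x3 convolutions, each followed by an activation
    (PReLU in the canonical VGG16-style block)."""

    def __init__(self, c_in: int, c_out: int, depth: int, rng: np.random.Generator,
                 activation="prelu"):
        if depth not in (2, 3):
            raise ValueError("VGG block depth must be 2 or 3")
        self.convs = []
        self.acts = []
        c = c_in
        for _ in range(depth):
            self.convs.append(nn.Conv2D(c, c_out, 3, rng))
            self.acts.append(_Activation(activation, c_out))
            c = c_out
        self.depth = depth
        self.out_channels = c_out

    def forward(self, x, training=False):
        for conv, act in zip(self.convs, self.acts):
            x = act(conv(x))
        return x


class DenseConvBlock(nn.Module):
    """Three [BN -> ReLU -> conv] units with dense concatenation.

    Kernels 5x5, 3x3, 1x1; every unit emits 64 channels; unit i consumes the
    concatenation of the block input and all previous unit outputs. The block
    output is the 64-channel result of the last unit, independent of the
    input width.
    """

    def __init__(self, c_in: int, rng: np.random.Generator):
        widths = [c_in, c_in + DENSE_CHANNELS, c_in + 2 * DENSE_CHANNELS]
        kernels = [5, 3, 1]
        self.bns = [nn.BatchNorm2D(w) for w in widths]
        self.convs = [
            nn.Conv2D(w, DENSE_CHANNELS, k, rng) for w, k in zip(widths, kernels)
        ]
        self.unit_input_channels = tuple(widths)
        self.out_channels = DENSE_CHANNELS

    def forward(self, x, training=False):
        feats = x
        out = x
        for bn, conv in zip(self.bns, self.convs):
            out = conv(F.relu(bn(feats, training)))
            feats = nn.concat([feats, out], axis=-1)
        return out


class MultiKernelInput(nn.Module):
    """Four parallel convolutions (kernels 1, 3, 5, 7), outputs concatenated.

    Each path has width m/4 so the concatenation matches the encoder's base
    width m.
    """

    KERNELS = (1, 3, 5, 7)

    def __init__(self, c_in: int, m: int, rng: np.random.Generator):
        if m % 4:
            raise ValueError("base channel count m must be divisible by 4")
        self.paths = [nn.Conv2D(c_in, m // 4, k, rng) for k in self.KERNELS]
        self.out_channels = m

    def forward(self, x, training=False):
        return nn.concat([F.relu(p(x)) for p in self.paths], axis=-1)


class AttentionGate(nn.Module):
    """Sigmoid spatial mask over encoder features, gated by the decoder.

    Both inputs are projected by 1x1 convolutions to an intermediate width
    (half the encoder width), added, passed through ReLU, a second 1x1
    convolution and a sigmoid; the resulting [0, 1] mask multiplies the
    encoder features element-wise. The gating signal, coming from one level
    below, is upsampled x2 (nearest) to match the encoder extent.
    """

    def __init__(self, enc_channels: int, gate_channels: int, rng: np.random.Generator):
        inter = max(1, enc_channels // 2)
        self.theta = nn.Conv2D(enc_channels, inter, 1, rng)
        self.phi = nn.Conv2D(gate_channels, inter, 1, rng)
        self.psi = nn.Conv2D(inter, 1, 1, rng)
        self.out_channels = enc_channels

    def forward(self, enc, gate, training=False):
        g = self.phi(gate)
        if g.shape[1] != enc.shape[1]:
            if g.shape[1] * 2 != enc.shape[1] or g.shape[2] * 2 != enc.shape[2]:
                raise ValueError(
                    f"gate extent {g.shape[1:3]} incompatible with encoder {enc.shape[1:3]}"
                )
            g = F.upsample_nearest2x(g)
        x = self.theta(enc)
        if x.shape != g.shape:
            raise ValueError("projected attention operands differ in shape")
        mask = F.sigmoid(self.psi(F.relu(nn.add(x, g))))
        return nn.mul(enc, mask)


class DSv1(nn.Module):
    """Deep-supervision signals S_n = conv1x1(C_n) + up(S_{n+1}); S_5 = conv1x1(C_5).

    Replaces the plain skip connections: S_n (width m) is what the decoder
    concatenates at level n.
    """

    def __init__(self, enc_channels: list[int], m: int, rng: np.random.Generator):
        self.convs = [nn.Conv2D(c, m, 1, rng) for c in enc_channels]
        self.out_channels = m

    def forward(self, C: list, training=False):
        n_levels = len(self.convs)
        S = [None] * n_levels
        S[-1] = self.convs[-1](C[-1])
        for n in range(n_levels - 2, -1, -1):
            S[n] = nn.add(self.convs[n](C[n]), F.upsample_nearest2x(S[n + 1]))
        return S


class DSv2(nn.Module):
    """Two-pass deep supervision.

    Bottom-up intermediates: prevS_5 = conv1x1(C_5),
    prevS_n = conv1x1(C_n) + up(prevS_{n+1}).
    Top-down signals: S_1 = prevS_1, S_n = prevS_n + max_pool(S_{n-1}).
    The 1x1 convolution per level is shared between the two passes (the two
    recursions name the identical term conv1x1(C_n) + up(prevS_{n+1})).
    """

    def __init__(self, enc_channels: list[int], m: int, rng: np.random.Generator):
        self.convs = [nn.Conv2D(c, m, 1, rng) for c in enc_channels]
        self.out_channels = m

    def forward(self, C: list, training=False):
        n_levels = len(self.convs)
        prevS = [None] * n_levels
        prevS[-1] = self.convs[-1](C[-1])
        for n in range(n_levels - 2, -1, -1):
            prevS[n] = nn.add(self.convs[n](C[n]), F.upsample_nearest2x(prevS[n + 1]))
        S = [None] * n_levels
        S[0] = prevS[0]
        for n in range(1, n_levels):
            S[n] = nn.add(prevS[n], F.max_pool2x2(S[n - 1]))
        return S


class DSv3(nn.Module):
    """Classification-input aggregation Z_n = conv1x1(T_n) + up(Z_{n+1}).

    Consumes the decoder outputs T_1..T_5 (T_5 = bottleneck) and returns Z_1,
    the enriched input to the classification block (width m, full extent).
    """

    def __init__(self, dec_channels: list[int], m: int, rng: np.random.Generator):
        self.convs = [nn.Conv2D(c, m, 1, rng) for c in dec_channels]
        self.out_channels = m

    def forward(self, T: list, training=False):
        n_levels = len(self.convs)
        Z = self.convs[-1](T[-1])
        for n in range(n_levels - 2, -1, -1):
            Z = nn.add(self.convs[n](T[n]), F.upsample_nearest2x(Z))
        return Z
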