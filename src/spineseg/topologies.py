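"""Assemble complete networks from the topology registry.

Thirteen configurations are registered, each a letter-coded combination of
blocks around a four-level encoder/decoder with a bottleneck:

=====  ==========================================  =========  ======  ======
ID     configuration                               optimizer  LR      act
=====  ==========================================  =========  ======  ======
UDD2   U-Net + DS.v3 + DS.v2                       Adam       3.3e-4  ReLU
UMDD   U-Net + multi-kernel + DS.v3 + DS.v1        Adam       3.3e-4  ReLU
UDD    U-Net + DS.v3 + DS.v1                       Adam       3.3e-4  ReLU
UQD    U-Net + dense blocks + DS.v3                Adam       3.3e-4  ReLU
UVDD   U-Net + VGG16 encoder + DS.v3 + DS.v1       Adam       3.3e-4  PReLU
UVMD   U-Net + VGG16 encoder + multi-kernel+DS.v3  Adam       3.3e-4  ReLU
UAMD   U-Net + attention + multi-kernel + DS.v3    Adam       3.3e-4  ReLU
UMD    U-Net + multi-kernel + DS.v3                Adam       3.3e-4  ReLU
UAD    U-Net + attention + DS.v3                   RMSprop    1e-3    ReLU
UD     U-Net + DS.v3                               Adam       3.3e-4  ReLU
UA     U-Net + attention gates                     Adam       3.3e-4  ReLU
U1     original U-Net                              Adadelta   1.0     ReLU
FCN    FCN8 (VGG16-style backbone)                 Adam       3.3e-4  ReLU
=====  ==========================================  =========  ======  ======

Networks take H x W x 2 inputs (T2w, T1w) and emit per-pixel softmax scores
over K classes. The base width m (64 in production) is configurable so the
whole stack runs at desk scale (m=8).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .blocks import (
    DENSE_CHANNELS,
    VGG_LEVEL_DEPTH,
    AttentionGate,
    DenseConvBlock,
    DSv1,
    DSv2,
    DSv3,
    MultiKernelInput,
    UNetConvBlock,
    VGGConvBlock,
)
from .nn import functional as F

LEVELS = 4  # encoder/decoder levels; level 5 is the bottleneck


class RegistryError(KeyError):
    """Unknown topology identifier."""


class ConfigError(ValueError):
    """Illegal block combination or contract violation."""


@dataclass(frozen=True)
class TopologySpec:
    id: str
    encoder_block: str = "U"  # U | V | Q
    decoder_block: str = "U"  # U | Q (V is encoder-only)
    use_multi_kernel: bool = False
    fusion: str = "skip"  # skip | attention | ds_v1 | ds_v2
    use_ds_v3: bool = False
    m: int = 64
    activation: str = "relu"
    optimizer_name: str = "adam"
    learning_rate: float = 0.00033
    is_fcn: bool = False

    def __post_init__(self):
        if self.encoder_block not in ("U", "V", "Q"):
            raise ConfigError(f"bad encoder block {self.encoder_block!r}")
        if self.decoder_block not in ("U", "Q"):
            raise ConfigError("decoder block must be U or Q (V is encoder-only)")
        if self.fusion not in ("skip", "attention", "ds_v1", "ds_v2"):
            raise ConfigError(f"bad fusion {self.fusion!r}")
        if self.encoder_block == "Q" and self.fusion in ("ds_v1", "ds_v2"):
            raise ConfigError("dense blocks cannot be combined with DS.v1/DS.v2")


_ADAM = dict(optimizer_name="adam", learning_rate=0.00033)

_REGISTRY: dict[str, TopologySpec] = {
    s.id: s
    for s in [
        TopologySpec("UDD2", fusion="ds_v2", use_ds_v3=True, **_ADAM),
        TopologySpec("UMDD", use_multi_kernel=True, fusion="ds_v1", use_ds_v3=True, **_ADAM),
        TopologySpec("UDD", fusion="ds_v1", use_ds_v3=True, **_ADAM),
        TopologySpec("UQD", encoder_block="Q", decoder_block="Q", use_ds_v3=True, **_ADAM),
        TopologySpec("UVDD", encoder_block="V", fusion="ds_v1", use_ds_v3=True,
                     activation="prelu", **_ADAM),
        TopologySpec("UVMD", encoder_block="V", use_multi_kernel=True, use_ds_v3=True, **_ADAM),
        TopologySpec("UAMD", use_multi_kernel=True, fusion="attention", use_ds_v3=True, **_ADAM),
        TopologySpec("UMD", use_multi_kernel=True, use_ds_v3=True, **_ADAM),
        TopologySpec("UAD", fusion="attention", use_ds_v3=True,
                     optimizer_name="rmsprop", learning_rate=0.001),
        TopologySpec("UD", use_ds_v3=True, **_ADAM),
        TopologySpec("UA", fusion="attention", **_ADAM),
        TopologySpec("U1", optimizer_name="adadelta", learning_rate=1.0),
        TopologySpec("FCN", is_fcn=True, **_ADAM),
    ]
}


def registry() -> list[TopologySpec]:
    """All registered topology configurations (13 entries)."""
    return list(_REGISTRY.values())


def get_spec(topology_id: str) -> TopologySpec:
    try:
        return _REGISTRY[topology_id]
    except KeyError:
        raise RegistryError(f"unknown topology id {topology_id!r}") from None


def _make_block(kind, c_in, c_out, level, rng, activation):
    if kind == "U":
        return UNetConvBlock(c_in, c_out, rng, activation=activation)
    if kind == "V":
        return VGGConvBlock(c_in, c_out, VGG_LEVEL_DEPTH[level], rng, activation=activation)
    if kind == "Q":
        return DenseConvBlock(c_in, rng)
    raise ConfigError(f"unknown block kind {kind!r}")


class UNetVariant(nn.Module):
    """A network built from a :class:`TopologySpec`.

    ``forward`` returns pre-softmax logits; ``predict_scores`` applies the
    softmax so every emitted score map is a per-pixel probability vector.
    The optional ``trace`` dict collects intermediate signals (encoder
    outputs ``C``, fusion signals ``S``, decoder outputs ``T``, DS.v3 output
    ``Z1``) for structural inspection.
    """

    def __init__(self, spec: TopologySpec, num_classes: int = 12,
                 input_channels: int = 2, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        self.num_classes = num_classes
        m = spec.m
        dense = spec.encoder_block == "Q"
        enc_ch = [DENSE_CHANNELS] * 5 if dense else [m * 2**n for n in range(5)]
        dec_dense = spec.decoder_block == "Q"
        dec_ch = [DENSE_CHANNELS] * 4 if dec_dense else [m * 2**n for n in range(4)]

        c_in = input_channels
        if spec.use_multi_kernel:
            self.multi_kernel = MultiKernelInput(c_in, m, rng)
            c_in = m

        self.encoder = []
        for lvl in range(1, 5):
            self.encoder.append(
                _make_block(spec.encoder_block, c_in, enc_ch[lvl - 1], lvl, rng,
                            spec.activation)
            )
            c_in = enc_ch[lvl - 1]
        self.bottleneck = _make_block(
            spec.encoder_block, enc_ch[3], enc_ch[4], 5, rng, spec.activation
        )

        if spec.fusion in ("ds_v1", "ds_v2"):
            ds_cls = DSv1 if spec.fusion == "ds_v1" else DSv2
            self.ds_fusion = ds_cls(enc_ch, m, rng)
            s_ch = [m] * 4
        elif spec.fusion == "attention":
            gate_ch = dec_ch[1:] + [enc_ch[4]]  # T_{n+1}; T5 is the bottleneck
            self.att_gates = [
                AttentionGate(enc_ch[n], gate_ch[n], rng) for n in range(4)
            ]
            s_ch = enc_ch[:4]
        else:
            s_ch = enc_ch[:4]

        # decoder level n: D_n = concat(S_n, transposed_conv(T_{n+1}))
        self.up_convs = []
        self.decoder = []
        for lvl in range(4, 0, -1):
            src = enc_ch[4] if lvl == 4 else dec_ch[lvl]  # channels of T_{n+1}
            self.up_convs.append(nn.ConvTranspose2D(src, dec_ch[lvl - 1], rng))
            d_in = s_ch[lvl - 1] + dec_ch[lvl - 1]
            self.decoder.append(
                _make_block(spec.decoder_block, d_in, dec_ch[lvl - 1], lvl, rng,
                            spec.activation)
            )

        if spec.use_ds_v3:
            self.ds_v3 = DSv3(dec_ch + [enc_ch[4]], m, rng)
            head_ch = m
        else:
            head_ch = dec_ch[0]
        self.feature_channels = head_ch
        self.classify = nn.Conv2D(head_ch, num_classes, 1, rng)

    # -- forward ---------------------------------------------------------
    def _check_extent(self, x):
        h, w = x.shape[1], x.shape[2]
        if h % 16 or w % 16:
            raise ConfigError(f"input extent {(h, w)} must be divisible by 16")

    def features(self, x, training=False, trace=None):
        """Pre-classification tensor (decoder top or DS.v3 output)."""
        x = nn.as_tensor(x)
        self._check_extent(x)
        spec = self.spec
        if spec.use_multi_kernel:
            x = self.multi_kernel(x, training)
        C = []
        for block in self.encoder:
            c = block(x, training)
            C.append(c)
            x = F.max_pool2x2(c)
        C5 = self.bottleneck(x, training)
        C = C + [C5]

        if spec.fusion in ("ds_v1", "ds_v2"):
            S = self.ds_fusion(C, training)[:4]
        elif spec.fusion == "attention":
            S = [None] * 4
        else:
            S = C[:4]

        T = [None] * 5
        T[4] = C5  # bottleneck passthrough
        for i, lvl in enumerate(range(4, 0, -1)):
            gate = T[lvl]
            if spec.fusion == "attention":
                S[lvl - 1] = self.att_gates[lvl - 1](C[lvl - 1], gate, training)
            up = self.up_convs[i](gate, training)
            d = nn.concat([S[lvl - 1], up], axis=-1)
            T[lvl - 1] = self.decoder[i](d, training)

        feat = self.ds_v3(T, training) if spec.use_ds_v3 else T[0]
        if trace is not None:
            trace.update(C=C, S=S, T=T, Z1=feat if spec.use_ds_v3 else None)
        return feat

    def forward(self, x, training=False, trace=None):
        """Logits of shape (N, H, W, K)."""
        return self.classify(self.features(x, training, trace))

    def predict_scores(self, x, batch_size: int = 8) -> np.ndarray:
        """Softmax scores for an (N, H, W, 2) array, evaluation mode."""
        x = np.asarray(x)
        outs = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward(nn.Tensor(x[lo : lo + batch_size]), training=False)
            outs.append(F.softmax(logits, axis=-1).data)
        return np.concatenate(outs, axis=0)


class FCN8(nn.Module):
    """FCN-8: VGG16-style backbone with score fusion at pool3/pool4/pool5.

    The channel schedule (m, 2m, 4m, 8m, 8m) reproduces the VGG16 widths at
    m=64. Scores from the stride-32 head are fused with 1x1-projected pool4
    and pool3 taps through learned x2 upsamplings, then upsampled x8 to full
    extent. Input extents must be divisible by 32.
    """

    def __init__(self, num_classes: int = 12, input_channels: int = 2,
                 m: int = 64, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = replace(_REGISTRY["FCN"], m=m)
        self.num_classes = num_classes
        widths = [m, 2 * m, 4 * m, 8 * m, 8 * m]
        depths = [2, 2, 3, 3, 3]
        self.stages = []
        c_in = input_channels
        for w, depth in zip(widths, depths):
            convs = []
            for _ in range(depth):
                convs.append(nn.Conv2D(c_in, w, 3, rng))
                c_in = w
            self.stages.append(convs)
        self.fc6 = nn.Conv2D(widths[4], 8 * m, 3, rng)
        self.fc7 = nn.Conv2D(8 * m, 8 * m, 1, rng)
        self.score_fr = nn.Conv2D(8 * m, num_classes, 1, rng)
        self.score_pool4 = nn.Conv2D(widths[3], num_classes, 1, rng)
        self.score_pool3 = nn.Conv2D(widths[2], num_classes, 1, rng)
        self.up_fr = nn.ConvTranspose2D(num_classes, num_classes, rng)
        self.up_fused4 = nn.ConvTranspose2D(num_classes, num_classes, rng)
        self.up_final = [
            nn.ConvTranspose2D(num_classes, num_classes, rng) for _ in range(3)
        ]
        self.feature_channels = None  # no pre-classification tensor of width m

    def forward(self, x, training=False, trace=None):
        x = nn.as_tensor(x)
        h, w = x.shape[1], x.shape[2]
        if h % 32 or w % 32:
            raise ConfigError(f"FCN8 input extent {(h, w)} must be divisible by 32")
        pools = []
        for convs in self.stages:
            for conv in convs:
                x = F.relu(conv(x))
            x = F.max_pool2x2(x)
            pools.append(x)
        x = F.relu(self.fc6(x))
        x = F.relu(self.fc7(x))
        score = self.score_fr(x)
        fused4 = nn.add(self.up_fr(score), self.score_pool4(pools[3]))
        fused3 = nn.add(self.up_fused4(fused4), self.score_pool3(pools[2]))
        out = fused3
        for up in self.up_final:
            out = up(out)
        if trace is not None:
            trace.update(pool3=pools[2], pool4=pools[3], pool5=pools[4])
        return out

    def predict_scores(self, x, batch_size: int = 8) -> np.ndarray:
        x = np.asarray(x)
        outs = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward(nn.Tensor(x[lo : lo + batch_size]), training=False)
            outs.append(F.softmax(logits, axis=-1).data)
        return np.concatenate(outs, axis=0)


def build_fcn8(num_classes: int = 12, input_channels: int = 2, m: int = 64,
               seed: int | None = None) -> FCN8:
    rng = np.random.default_rng(seed)
    return FCN8(num_classes, input_channels, m, rng)


def build_topology(topology_id: str, m: int = 64, num_classes: int = 12,
                   input_channels: int = 2, seed: int | None = None):
    """Instantiate a registered topology with freshly initialised weights."""
    spec = replace(get_spec(topology_id), m=m)
    rng = np.random.default_rng(seed)
    if spec.is_fcn:
        return FCN8(num_classes, input_channels, m, rng)
    return UNetVariant(spec, num_classes, input_channels, rng)
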