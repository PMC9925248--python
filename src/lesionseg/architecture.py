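"""The encoder-decoder segmentation network.

Encoder: four stages, each running three parallel branches on the stage
input — (a) a 1x1 convolution + ReLU + stride-1 3x3 max-pool, (b) a
depthwise-separable convolution (DSC) block and (c) a multi-dilated
convolution (MDC) block — whose outputs are concatenated, then 2x2
max-pooled and dropped out.  A bottleneck of the same three-branch shape
sits at 1/16 resolution.  Decoder: four stages of 3x3 stride-2 transposed
convolution, concatenation with the matching encoder stage's pre-pool
features, then MDC + DSC.  A 1x1 convolution + sigmoid head emits a
one-channel probability map.

Regular and dilated convolutions are He-normal initialized; depthwise
separable ones use Glorot/Xavier uniform.  An all-Glorot switch is
provided (``init_scheme="glorot"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .activations import glorot_uniform, he_normal
from .nn import Module, Tensor

__all__ = [
    "ModelConfig",
    "NetworkSummary",
    "DSCBlock",
    "MDCBlock",
    "build_dsc_block",
    "build_mdc_block",
    "build_model",
    "summarize",
    "SegmentationModel",
]


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 256
    in_channels: int = 3
    filter_ladder: tuple = (16, 32, 64, 128)
    dilation_rates: tuple = (1, 2, 3)
    dropout_rate: float = 0.05
    pool_size: int = 2
    transposed_kernel: int = 3
    transposed_stride: int = 2
    init_scheme: str = "paper"  # "paper" = He for regular/MDC, Glorot for DSC
    mdc_wiring: str = "concat_input"  # or "chain": feed only the previous output
    mdc_mode: str = "rates"  # "rates": 3x3 kernels at rates 1,2,3; "kernels": sizes 1,2,3
    use_separable: bool = True  # False swaps DSC blocks for standard 3x3 convs

    def __post_init__(self):
        down = self.pool_size ** len(self.filter_ladder)
        if self.input_size % down != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by {down}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.init_scheme not in ("paper", "glorot"):
            raise ValueError("init_scheme must be 'paper' or 'glorot'")
        if self.mdc_wiring not in ("concat_input", "chain"):
            raise ValueError("mdc_wiring must be 'concat_input' or 'chain'")

    @property
    def bottleneck_size(self):
        return self.input_size // self.pool_size ** len(self.filter_ladder)


@dataclass
class NetworkSummary:
    layer_shapes: dict
    total_parameters: int
    bottleneck_spatial: int

    def to_tsv(self):
        lines = ["layer\tshape"]
        for name, shape in self.layer_shapes.items():
            lines.append(f"{name}\t{'x'.join(str(s) for s in shape)}")
        lines.append(f"total_parameters\t{self.total_parameters}")
        lines.append(f"bottleneck_spatial\t{self.bottleneck_spatial}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# weight construction
# ---------------------------------------------------------------------------

def _he_conv(rng, in_ch, out_ch, k, dilation=1):
    w = he_normal(rng, in_ch * k * k, (out_ch, in_ch, k, k))
    return nn.Conv2d(in_ch, out_ch, k, dilation=dilation, weight=w)


def _glorot_conv(rng, in_ch, out_ch, k, dilation=1):
    w = glorot_uniform(rng, in_ch * k * k, out_ch * k * k, (out_ch, in_ch, k, k))
    return nn.Conv2d(in_ch, out_ch, k, dilation=dilation, weight=w)


def _regular_conv(rng, in_ch, out_ch, k, dilation=1, scheme="paper"):
    # regular/dilated convolutions: He normal by default, Glorot when forced
    if scheme == "glorot":
        return _glorot_conv(rng, in_ch, out_ch, k, dilation=dilation)
    return _he_conv(rng, in_ch, out_ch, k, dilation=dilation)


class DSCBlock(Module):
    """3x3 depthwise per channel, then 1x1 pointwise projection, then swish."""

    def __init__(self, in_channels, out_channels, rng, scheme="paper"):
        # DSC weights are Glorot-initialized under both schemes
        k = 3
        dw_w = glorot_uniform(rng, k * k, k * k, (in_channels, k, k))
        self.pointwise = _glorot_conv(rng, in_channels, out_channels, 1)
        self.depthwise = nn.DepthwiseConv2d(in_channels, k, weight=dw_w)
        self.in_channels = in_channels
        self.out_channels = out_channels

    def __call__(self, x, training=False):
        return nn.swish(self.pointwise(self.depthwise(x)))


class StandardBlock(Module):
    """Plain 3x3 convolution + swish; the non-separable stand-in for DSCBlock."""

    def __init__(self, in_channels, out_channels, rng):
        self.conv = _he_conv(rng, in_channels, out_channels, 3)

    def __call__(self, x, training=False):
        return nn.swish(self.conv(x))


class MDCBlock(Module):
    """Chained dilated convolutions with batch norm + swish after each.

    With the default wiring, dilated convolution n >= 2 consumes the
    concatenation of the block input and the previous dilated output.
    """

    def __init__(
        self,
        in_channels,
        out_channels,
        rng,
        rates=(1, 2, 3),
        wiring="concat_input",
        mode="rates",
        scheme="paper",
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.wiring = wiring
        convs, bns = [], []
        for i, r in enumerate(rates):
            if i == 0:
                c_in = in_channels
            elif wiring == "concat_input":
                c_in = in_channels + out_channels
            else:
                c_in = out_channels
            if mode == "rates":
                convs.append(
                    _regular_conv(rng, c_in, out_channels, 3, dilation=r, scheme=scheme)
                )
            else:  # literal kernel sizes 1, 2, 3 — even sizes rounded up to odd
                k = r if r % 2 == 1 else r + 1
                convs.append(_regular_conv(rng, c_in, out_channels, k, scheme=scheme))
            bns.append(nn.BatchNorm2d(out_channels))
        self.convs = convs
        self.bns = bns

    def __call__(self, x, training=False):
        d = None
        for conv, bn in zip(self.convs, self.bns):
            if d is None:
                inp = x
            elif self.wiring == "concat_input":
                inp = nn.concat([x, d])
            else:
                inp = d
            d = nn.swish(bn(conv(inp), training=training))
        return d


def build_dsc_block(in_channels, out_channels, seed=0):
    if in_channels < 1 or out_channels < 1:
        raise ValueError("channel counts must be positive")
    return DSCBlock(in_channels, out_channels, np.random.default_rng(seed))


def build_mdc_block(in_channels, out_channels, rates=(1, 2, 3), seed=0):
    if in_channels < 1 or out_channels < 1:
        raise ValueError("channel counts must be positive")
    if len(rates) == 0:
        raise ValueError("rates must be non-empty")
    return MDCBlock(in_channels, out_channels, np.random.default_rng(seed), rates=rates)


class EncoderStage(Module):
    """Parallel {1x1 conv + 3x3 max-pool, DSC, MDC} branches, concatenated."""

    def __init__(self, in_channels, filters, config, rng):
        self.conv1x1 = _regular_conv(
            rng, in_channels, filters, 1, scheme=config.init_scheme
        )
        if config.use_separable:
            self.dsc = DSCBlock(in_channels, filters, rng, scheme=config.init_scheme)
        else:
            self.dsc = StandardBlock(in_channels, filters, rng)
        self.mdc = MDCBlock(
            in_channels,
            filters,
            rng,
            rates=config.dilation_rates,
            wiring=config.mdc_wiring,
            mode=config.mdc_mode,
            scheme=config.init_scheme,
        )
        self.out_channels = 3 * filters

    def __call__(self, x, training=False):
        a = nn.maxpool_same(nn.relu(self.conv1x1(x)), 3)
        b = self.dsc(x, training=training)
        c = self.mdc(x, training=training)
        return nn.concat([a, b, c])


class DecoderStage(Module):
    """Transposed conv upsampling, skip concatenation, then MDC + DSC."""

    def __init__(self, in_channels, skip_channels, filters, config, rng):
        k, s = config.transposed_kernel, config.transposed_stride
        if config.init_scheme == "glorot":
            w = glorot_uniform(
                rng, in_channels * k * k, filters * k * k, (filters, in_channels, k, k)
            )
        else:
            w = he_normal(rng, in_channels * k * k, (filters, in_channels, k, k))
        self.up = nn.ConvTranspose2d(in_channels, filters, k, s, weight=w)
        cat_ch = filters + skip_channels
        self.mdc = MDCBlock(
            cat_ch,
            filters,
            rng,
            rates=config.dilation_rates,
            wiring=config.mdc_wiring,
            mode=config.mdc_mode,
            scheme=config.init_scheme,
        )
        if config.use_separable:
            self.dsc = DSCBlock(filters, filters, rng, scheme=config.init_scheme)
        else:
            self.dsc = StandardBlock(filters, filters, rng)
        self.out_channels = filters

    def __call__(self, x, skip, training=False):
        up = self.up(x)
        cat = nn.concat([up, skip])
        return self.dsc(self.mdc(cat, training=training), training=training)


class SegmentationModel(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ladder = list(config.filter_ladder)

        self.encoder = []
        ch = config.in_channels
        for f in ladder:
            stage = EncoderStage(ch, f, config, rng)
            self.encoder.append(stage)
            ch = stage.out_channels
        self.dropouts = [
            nn.Dropout(config.dropout_rate, seed=seed + 101 + i)
            for i in range(len(ladder))
        ]

        bottleneck_filters = 2 * ladder[-1]
        self.bottleneck = EncoderStage(ch, bottleneck_filters, config, rng)
        ch = self.bottleneck.out_channels

        self.decoder = []
        for i in reversed(range(len(ladder))):
            stage = DecoderStage(ch, 3 * ladder[i], ladder[i], config, rng)
            self.decoder.append(stage)
            ch = stage.out_channels

        self.head = _regular_conv(rng, ch, 1, 1, scheme=config.init_scheme)
        self._capture = None

    def reseed_dropout(self, seed):
        for i, d in enumerate(self.dropouts):
            d.reseed(seed + 101 + i)

    def forward(self, x: Tensor, training: bool = False, capture: bool = False):
        shapes = {} if capture else None
        skips = []
        t = x
        for i, (stage, drop) in enumerate(zip(self.encoder, self.dropouts)):
            feats = stage(t, training=training)
            skips.append(feats)
            t = drop(nn.maxpool2d(feats, self.config.pool_size), training=training)
            if capture:
                shapes[f"encoder{i + 1}"] = feats.shape
                shapes[f"pool{i + 1}"] = t.shape
        t = self.bottleneck(t, training=training)
        if capture:
            shapes["bottleneck"] = t.shape
        for i, stage in enumerate(self.decoder):
            t = stage(t, skips[-(i + 1)], training=training)
            if capture:
                shapes[f"decoder{i + 1}"] = t.shape
        out = nn.sigmoid(self.head(t))
        if capture:
            shapes["output"] = out.shape
            self._capture = shapes
        return out

    def __call__(self, x, training=False):
        return self.forward(x, training=training)

    def predict_proba(self, images):
        """Probability maps for (B, S, S, 3) or (S, S, 3) images in [0, 1]."""
        arr = np.asarray(images, dtype=np.float32)
        single = arr.ndim == 3
        if single:
            arr = arr[None]
        x = Tensor(arr.transpose(0, 3, 1, 2))
        probs = self.forward(x, training=False).data[:, 0]
        return probs[0] if single else probs


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SegmentationModel:
    if config is None:
        config = ModelConfig()
    return SegmentationModel(config, seed=seed)


def summarize(model: SegmentationModel) -> NetworkSummary:
    """Run a dummy forward pass with shape capture and tally parameters."""
    cfg = model.config
    x = Tensor(
        np.zeros((1, cfg.in_channels, cfg.input_size, cfg.input_size), dtype=np.float32)
    )
    model.forward(x, training=False, capture=True)
    shapes = model._capture
    out_side = shapes["output"][-1]
    if out_side != cfg.input_size:
        raise AssertionError("decoder failed to restore the input resolution")
    return NetworkSummary(
        layer_shapes=shapes,
        total_parameters=model.num_parameters(),
        bottleneck_spatial=shapes["bottleneck"][-1],
    )
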