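"""Convolutional branch: MBConv/EfficientNet-style encoder and CNN decoder.

The encoder is a compound-scaled stack of mobile inverted bottleneck blocks
(expand 1x1 -> depthwise kxk -> squeeze-excite -> project 1x1, Swish
activations, BN after every conv).  Width is rounded to multiples of 8 with
the usual "make divisible" rule and depth is rounded up, reproducing the
published b0-b3 configurations.  A side tap after the last block at each
stride yields the feature pyramid consumed by the decoders.

The decoder block is the U-Net style unit the dual-branch model uses on the
CNN side: 2x upsampling, skip fusion by channel concatenation, then two 3x3
conv + BN + ReLU layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import nn
from .nn import Tensor, as_tensor


@dataclass
class FeatureMap:
    """Dense channels x height x width features at a known stride."""

    data: Tensor  # (N, C, H, W)
    stride: int

    def __post_init__(self):
        self.data = as_tensor(self.data)
        if self.data.ndim != 4:
            raise ValueError("FeatureMap expects NCHW data")
        if self.stride not in (1, 2, 4, 8, 16, 32):
            raise ValueError(f"unsupported stride {self.stride}")

    @property
    def channels(self) -> int:
        return self.data.shape[1]


@dataclass
class FeaturePyramid:
    """Ordered multi-scale features at strictly increasing strides."""

    levels: list[FeatureMap]

    def __post_init__(self):
        strides = [f.stride for f in self.levels]
        if strides != sorted(set(strides)):
            raise ValueError(f"strides must strictly increase, got {strides}")

    def at_stride(self, stride: int) -> FeatureMap:
        for f in self.levels:
            if f.stride == stride:
                return f
        raise KeyError(f"no pyramid level at stride {stride}")

    @property
    def strides(self) -> list[int]:
        return [f.stride for f in self.levels]


@dataclass
class MBConvSpec:
    expand_ratio: int
    kernel_size: int
    stride: int
    in_channels: int
    out_channels: int
    se_ratio: float = 0.25

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("MBConv stride must be 1 or 2")

    @property
    def expanded(self) -> int:
        return make_divisible(self.in_channels * self.expand_ratio) \
            if self.expand_ratio != 1 else self.in_channels

    @property
    def use_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels

    def parameter_count(self) -> int:
        """Closed-form trainable-parameter count of one block."""
        exp = self.expanded
        n = 0
        if self.expand_ratio != 1:
            n += self.in_channels * exp + 2 * exp          # 1x1 expand + BN
        n += self.kernel_size ** 2 * exp + 2 * exp         # depthwise + BN
        if self.se_ratio > 0:
            sq = max(1, int(self.in_channels * self.se_ratio))
            n += exp * sq + sq + sq * exp + exp            # SE fc1 + fc2 (biased)
        n += exp * self.out_channels + 2 * self.out_channels  # 1x1 project + BN
        return n


def make_divisible(v: float, divisor: int = 8) -> int:
    """Round channel counts to multiples of ``divisor``, never below 90 %."""
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class SqueezeExcite(nn.Module):
    """Channel gating: global pool -> fc (SiLU) -> fc (sigmoid) -> scale."""

    def __init__(self, channels: int, squeeze_channels: int, rng=None):
        super().__init__()
        self.fc1 = nn.Conv2d(channels, squeeze_channels, 1, rng=rng)
        self.fc2 = nn.Conv2d(squeeze_channels, channels, 1, rng=rng)
        self.act = nn.SiLU()

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3), keepdims=True)
        s = nn.sigmoid(self.fc2(self.act(self.fc1(s))))
        return x * s


class ConvBNAct(nn.Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 groups: int = 1, act: str = "silu", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, stride=stride,
                              padding=kernel // 2, groups=groups, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = {"silu": nn.SiLU, "relu": nn.ReLU, "none": nn.Identity}[act]()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class MBConv(nn.Module):
    """Mobile inverted bottleneck convolution with squeeze-excitation."""

    def __init__(self, spec: MBConvSpec, rng=None):
        super().__init__()
        self.spec = spec
        exp = spec.expanded
        if spec.expand_ratio != 1:
            self.expand = ConvBNAct(spec.in_channels, exp, 1, rng=rng)
        else:
            self.expand = nn.Identity()
        self.depthwise = ConvBNAct(exp, exp, spec.kernel_size, stride=spec.stride,
                                   groups=exp, rng=rng)
        if spec.se_ratio > 0:
            sq = max(1, int(spec.in_channels * spec.se_ratio))
            self.se = SqueezeExcite(exp, sq, rng=rng)
        else:
            self.se = nn.Identity()
        self.project = ConvBNAct(exp, spec.out_channels, 1, act="none", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(f"MBConv expects {self.spec.in_channels} channels, "
                             f"got {x.shape[1]}")
        out = self.project(self.se(self.depthwise(self.expand(x))))
        if self.spec.use_residual:
            out = out + x
        return out


# stage table of the base (b0) network: expand, kernel, stride, in, out, repeats
_BASE_STAGES = [
    (1, 3, 1, 32, 16, 1),
    (6, 3, 2, 16, 24, 2),
    (6, 5, 2, 24, 40, 2),
    (6, 3, 2, 40, 80, 3),
    (6, 5, 1, 80, 112, 3),
    (6, 5, 2, 112, 192, 4),
    (6, 3, 1, 192, 320, 1),
]

# (width multiplier, depth multiplier); resolution handled by the caller
VARIANTS = {
    "b0": (1.0, 1.0),
    "b1": (1.0, 1.1),
    "b2": (1.1, 1.2),
    "b3": (1.2, 1.4),
    # desk-scale configuration for tests/toys: narrow and one block per stage
    "tiny": (0.25, 0.25),
}


def variant_stage_specs(variant: str) -> tuple[int, list[list[MBConvSpec]]]:
    """Stem width and per-stage MBConv specs for a named variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; supported: "
                         f"{sorted(VARIANTS)}")
    wm, dm = VARIANTS[variant]
    stem = make_divisible(32 * wm)
    cin = stem
    stages = []
    for expand, kernel, stride, _, out, repeats in _BASE_STAGES:
        cout = make_divisible(out * wm)
        reps = int(math.ceil(dm * repeats))
        specs = []
        for r in range(reps):
            specs.append(MBConvSpec(expand, kernel, stride if r == 0 else 1,
                                    cin, cout))
            cin = cout
        stages.append(specs)
    return stem, stages


class EfficientNet(nn.Module):
    """Compound-scaled MBConv network (b0-b3 plus a desk-scale 'tiny').

    ``forward`` returns class logits when built with a head;
    ``forward_features`` returns the multi-scale pyramid with taps at the
    last block of each stride plus the bottleneck (highest-stride) map.
    """

    def __init__(self, variant: str = "b0", in_channels: int = 3,
                 num_classes: int = 1000, include_head: bool = True,
                 max_stride: int = 32, rng=None):
        super().__init__()
        self.variant = variant
        self.max_stride = max_stride
        stem_ch, stages = variant_stage_specs(variant)
        self.stem = ConvBNAct(in_channels, stem_ch, 3, stride=2, rng=rng)

        self.blocks = nn.ModuleList()
        self._block_strides: list[int] = []
        stride = 2
        self._out_channels = stem_ch
        truncated = False
        for specs in stages:
            if truncated:
                break
            for spec in specs:
                new_stride = stride * spec.stride
                if new_stride > max_stride:
                    truncated = True
                    break
                stride = new_stride
                self.blocks.append(MBConv(spec, rng=rng))
                self._block_strides.append(stride)
                self._out_channels = spec.out_channels

        if include_head:
            head_ch = 4 * self._out_channels
            self.head_conv = ConvBNAct(self._out_channels, head_ch, 1, rng=rng)
            self.classifier = nn.Linear(head_ch, num_classes, rng=rng)
        else:
            self.head_conv = None
            self.classifier = None

    @property
    def pyramid_channels(self) -> dict[int, int]:
        """Channels of the tap at each stride."""
        out = {}
        for blk, s in zip(self.blocks, self._block_strides):
            out[s] = blk.spec.out_channels
        return out

    def forward_features(self, image: Tensor) -> FeaturePyramid:
        x = self.stem(as_tensor(image))
        taps: dict[int, Tensor] = {}
        for blk, s in zip(self.blocks, self._block_strides):
            x = blk(x)
            taps[s] = x  # last block at each stride wins
        levels = [FeatureMap(taps[s], s) for s in sorted(taps)]
        return FeaturePyramid(levels)

    def forward(self, image: Tensor) -> Tensor:
        if self.head_conv is None:
            raise RuntimeError("network built without classification head")
        pyr = self.forward_features(image)
        x = self.head_conv(pyr.levels[-1].data)
        return self.classifier(nn.global_avg_pool(x))


def efficientnet_encode(image: Tensor, variant: str = "b3", rng=None
                        ) -> tuple[FeaturePyramid, FeatureMap]:
    """One-shot encode: pyramid at strides {4, 8, 16, 32} + bottleneck."""
    net = EfficientNet(variant, include_head=False, rng=rng)
    pyr = net.forward_features(image)
    deep = [f for f in pyr.levels if f.stride >= 4]
    pyr = FeaturePyramid(deep)
    return pyr, pyr.levels[-1]


class CNNDecoderBlock(nn.Module):
    """2x upsample -> skip concat -> two (3x3 conv + BN + ReLU) layers."""

    def __init__(self, in_channels: int, skip_channels: int, out_channels: int,
                 upsample: str = "bilinear", rng=None):
        super().__init__()
        if upsample not in ("bilinear", "transpose"):
            raise ValueError("upsample must be 'bilinear' or 'transpose'")
        self.upsample = upsample
        if upsample == "transpose":
            self.up = nn.ConvTranspose2x2(in_channels, in_channels, rng=rng)
        else:
            self.up = None
        self.skip_channels = skip_channels
        self.conv1 = ConvBNAct(in_channels + skip_channels, out_channels, 3,
                               act="relu", rng=rng)
        self.conv2 = ConvBNAct(out_channels, out_channels, 3, act="relu", rng=rng)

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        n, c, h, w = x.shape
        x = self.up(x) if self.up is not None else \
            nn.interpolate_bilinear(x, 2 * h, 2 * w)
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(f"skip spatial dims {skip.shape[2:]} do not "
                                 f"match upsampled input {x.shape[2:]}")
            x = nn.concat([x, skip], axis=1)
        elif self.skip_channels:
            raise ValueError("block built with skip channels but none given")
        return self.conv2(self.conv1(x))


class SegHead(nn.Module):
    """Final 1x1 convolution to per-pixel class logits (unnormalised)."""

    def __init__(self, in_channels: int, num_classes: int, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, num_classes, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)
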