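"""Layer-by-layer parameter ledgers for standard classification backbones.

The dual-branch model's ablation compares candidate CNN encoders by their
trainable-parameter budgets (in millions).  This module reconstructs those
budgets analytically from the published architectures — every convolution,
batch norm and fully connected layer is enumerated with its exact parameter
count, in the standard full-classification configuration (1000 classes,
ImageNet layout) so the totals are comparable to commonly quoted numbers.

EfficientNet counts come from the real implementation in :mod:`onet.cnn`;
the others (ResNet-50, DenseNet-201, MobileNetV3-Large, Inception v3) are
count-only ledgers: they enumerate layers without allocating weights.
"""

from __future__ import annotations

from .cnn import EfficientNet, make_divisible

Ledger = list[tuple[str, int]]


def _conv(cin: int, cout: int, k, groups: int = 1, bias: bool = False) -> int:
    kh, kw = (k, k) if isinstance(k, int) else k
    n = (cin // groups) * cout * kh * kw
    return n + (cout if bias else 0)


def _bn(c: int) -> int:
    return 2 * c


def _fc(cin: int, cout: int) -> int:
    return cin * cout + cout


# ---------------------------------------------------------------------------
# ResNet-50
# ---------------------------------------------------------------------------

def resnet50_ledger(num_classes: int = 1000) -> Ledger:
    """Bottleneck ResNet: stem 7x7/2, stages [3, 4, 6, 3], expansion 4."""
    ledger: Ledger = [("conv1", _conv(3, 64, 7)), ("bn1", _bn(64))]
    cin = 64
    for stage, (planes, blocks) in enumerate(
            zip((64, 128, 256, 512), (3, 4, 6, 3)), start=1):
        cout = planes * 4
        for b in range(blocks):
            name = f"layer{stage}.{b}"
            n = (_conv(cin, planes, 1) + _bn(planes)
                 + _conv(planes, planes, 3) + _bn(planes)
                 + _conv(planes, cout, 1) + _bn(cout))
            if b == 0:  # projection shortcut
                n += _conv(cin, cout, 1) + _bn(cout)
            ledger.append((name, n))
            cin = cout
    ledger.append(("fc", _fc(cin, num_classes)))
    return ledger


# ---------------------------------------------------------------------------
# DenseNet-201
# ---------------------------------------------------------------------------

def densenet201_ledger(num_classes: int = 1000) -> Ledger:
    """Dense blocks (6, 12, 48, 32), growth 32, bottleneck factor 4."""
    growth, bn_size = 32, 4
    ledger: Ledger = [("conv0", _conv(3, 64, 7)), ("norm0", _bn(64))]
    cin = 64
    for i, layers in enumerate((6, 12, 48, 32), start=1):
        for j in range(layers):
            n = (_bn(cin) + _conv(cin, bn_size * growth, 1)
                 + _bn(bn_size * growth) + _conv(bn_size * growth, growth, 3))
            ledger.append((f"denseblock{i}.layer{j}", n))
            cin += growth
        if i < 4:
            ledger.append((f"transition{i}", _bn(cin) + _conv(cin, cin // 2, 1)))
            cin //= 2
    ledger.append(("norm5", _bn(cin)))
    ledger.append(("classifier", _fc(cin, num_classes)))
    return ledger


# ---------------------------------------------------------------------------
# MobileNetV3-Large
# ---------------------------------------------------------------------------

# input ch, kernel, expanded ch, out ch, squeeze-excite, stride
_MBV3_LARGE = [
    (16, 3, 16, 16, False, 1),
    (16, 3, 64, 24, False, 2),
    (24, 3, 72, 24, False, 1),
    (24, 5, 72, 40, True, 2),
    (40, 5, 120, 40, True, 1),
    (40, 5, 120, 40, True, 1),
    (40, 3, 240, 80, False, 2),
    (80, 3, 200, 80, False, 1),
    (80, 3, 184, 80, False, 1),
    (80, 3, 184, 80, False, 1),
    (80, 3, 480, 112, True, 1),
    (112, 3, 672, 112, True, 1),
    (112, 5, 672, 160, True, 2),
    (160, 5, 960, 160, True, 1),
    (160, 5, 960, 160, True, 1),
]


def mobilenetv3_large_ledger(num_classes: int = 1000) -> Ledger:
    ledger: Ledger = [("stem", _conv(3, 16, 3) + _bn(16))]
    for i, (cin, k, exp, cout, se, _stride) in enumerate(_MBV3_LARGE):
        n = 0
        if exp != cin:
            n += _conv(cin, exp, 1) + _bn(exp)
        n += _conv(exp, exp, k, groups=exp) + _bn(exp)
        if se:
            sq = make_divisible(exp // 4)
            n += _conv(exp, sq, 1, bias=True) + _conv(sq, exp, 1, bias=True)
        n += _conv(exp, cout, 1) + _bn(cout)
        ledger.append((f"block{i}", n))
    ledger.append(("last_conv", _conv(160, 960, 1) + _bn(960)))
    ledger.append(("pre_classifier", _fc(960, 1280)))
    ledger.append(("classifier", _fc(1280, num_classes)))
    return ledger


# ---------------------------------------------------------------------------
# Inception v3
# ---------------------------------------------------------------------------

def _basic(cin: int, cout: int, k) -> int:
    """Conv (no bias) + BN pair used throughout Inception v3."""
    return _conv(cin, cout, k) + _bn(cout)


def _inception_a(cin: int, pool_features: int) -> int:
    return (_basic(cin, 64, 1)
            + _basic(cin, 48, 1) + _basic(48, 64, 5)
            + _basic(cin, 64, 1) + _basic(64, 96, 3) + _basic(96, 96, 3)
            + _basic(cin, pool_features, 1))


def _inception_b(cin: int) -> int:
    return (_basic(cin, 384, 3)
            + _basic(cin, 64, 1) + _basic(64, 96, 3) + _basic(96, 96, 3))


def _inception_c(cin: int, c7: int) -> int:
    return (_basic(cin, 192, 1)
            + _basic(cin, c7, 1) + _basic(c7, c7, (1, 7)) + _basic(c7, 192, (7, 1))
            + _basic(cin, c7, 1) + _basic(c7, c7, (7, 1)) + _basic(c7, c7, (1, 7))
            + _basic(c7, c7, (7, 1)) + _basic(c7, 192, (1, 7))
            + _basic(cin, 192, 1))


def _inception_d(cin: int) -> int:
    return (_basic(cin, 192, 1) + _basic(192, 320, 3)
            + _basic(cin, 192, 1) + _basic(192, 192, (1, 7))
            + _basic(192, 192, (7, 1)) + _basic(192, 192, 3))


def _inception_e(cin: int) -> int:
    return (_basic(cin, 320, 1)
            + _basic(cin, 384, 1) + _basic(384, 384, (1, 3)) + _basic(384, 384, (3, 1))
            + _basic(cin, 448, 1) + _basic(448, 384, 3)
            + _basic(384, 384, (1, 3)) + _basic(384, 384, (3, 1))
            + _basic(cin, 192, 1))


def inception_v3_ledger(num_classes: int = 1000) -> Ledger:
    """Inception v3 without the auxiliary training head."""
    return [
        ("Conv2d_1a", _basic(3, 32, 3)),
        ("Conv2d_2a", _basic(32, 32, 3)),
        ("Conv2d_2b", _basic(32, 64, 3)),
        ("Conv2d_3b", _basic(64, 80, 1)),
        ("Conv2d_4a", _basic(80, 192, 3)),
        ("Mixed_5b", _inception_a(192, 32)),
        ("Mixed_5c", _inception_a(256, 64)),
        ("Mixed_5d", _inception_a(288, 64)),
        ("Mixed_6a", _inception_b(288)),
        ("Mixed_6b", _inception_c(768, 128)),
        ("Mixed_6c", _inception_c(768, 160)),
        ("Mixed_6d", _inception_c(768, 160)),
        ("Mixed_6e", _inception_c(768, 192)),
        ("Mixed_7a", _inception_d(768)),
        ("Mixed_7b", _inception_e(1280)),
        ("Mixed_7c", _inception_e(2048)),
        ("fc", _fc(2048, num_classes)),
    ]


# ---------------------------------------------------------------------------
# public interface
# ---------------------------------------------------------------------------

_LEDGERS = {
    "resnet50": resnet50_ledger,
    "densenet201": densenet201_ledger,
    "mobilenetv3": mobilenetv3_large_ledger,
    "inception_v3": inception_v3_ledger,
}


def backbone_parameter_count(name: str, num_classes: int = 1000) -> int:
    """Total trainable parameters of a named backbone.

    ``efficientnet-b0``..``b3`` instantiate the real network; the rest are
    analytic ledgers of the published layer layouts.
    """
    name = name.lower()
    if name.startswith("efficientnet-"):
        return EfficientNet(name.split("-", 1)[1],
                            num_classes=num_classes).num_parameters()
    if name in _LEDGERS:
        return sum(n for _, n in _LEDGERS[name](num_classes))
    raise ValueError(f"unknown backbone {name!r}; supported: "
                     f"{sorted(_LEDGERS) + ['efficientnet-b0..b3']}")


def backbone_parameter_millions(name: str) -> float:
    """Parameter count in millions, rounded to 2 decimals as usually quoted."""
    return round(backbone_parameter_count(name) / 1e6, 2)
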