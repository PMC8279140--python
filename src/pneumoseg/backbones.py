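"""Encoder backbones for the segmentation U-Nets.

Each encoder is a classification network truncated before global pooling
and the classifier, exposing five feature taps at strides 2, 4, 8, 16 and
32.  Tap placement follows the backbone-U-Net convention that reproduces
the reference models' parameter budgets:

* ResNet-50 / SE-ResNeXt: stem ReLU and the outputs of the first three
  residual stages; the final stage is the bottleneck.
* DenseNet-169: stem ReLU and the transition-layer 1x1 compression
  outputs taken before their pooling; the bottleneck is the final
  BN-ReLU feature map.
* EfficientNet: the expansion activations of the first block of each
  stride-2 stage; the bottleneck is the 1x1 head convolution output.

``tiny`` is a deliberately small plain-conv encoder for fast CPU training
runs and smoke tests; it honors the same five-tap contract.
"""

from __future__ import annotations

import math

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Identity,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Sigmoid,
    SiLU,
)
from .nn import autograd as ag

__all__ = ["build_encoder", "ENCODERS"]


def _conv_bn(in_ch, out_ch, kernel, stride=1, groups=1, act=ReLU):
    mods = [
        Conv2d(in_ch, out_ch, kernel, stride=stride, groups=groups, bias=False),
        BatchNorm2d(out_ch),
    ]
    if act is not None:
        mods.append(act())
    return Sequential(*mods)


class SqueezeExcite(Module):
    """Channel re-weighting: global pool -> bottleneck MLP -> sigmoid scale."""

    def __init__(self, channels: int, squeeze: int, act=ReLU):
        super().__init__()
        self.pool = GlobalAvgPool()
        self.fc1 = Conv2d(channels, squeeze, 1)
        self.act = act()
        self.fc2 = Conv2d(squeeze, channels, 1)
        self.gate = Sigmoid()

    def forward(self, x):
        s = self.gate(self.fc2(self.act(self.fc1(self.pool(x)))))
        return x * s


# ---------------------------------------------------------------- ResNet
class Bottleneck(Module):
    """1x1 -> 3x3 (stride, optionally grouped) -> 1x1 with residual add."""

    def __init__(self, in_ch, width, out_ch, stride=1, groups=1, se_reduction=0):
        super().__init__()
        self.conv1 = _conv_bn(in_ch, width, 1)
        self.conv2 = _conv_bn(width, width, 3, stride=stride, groups=groups)
        self.conv3 = _conv_bn(width, out_ch, 1, act=None)
        self.se = SqueezeExcite(out_ch, out_ch // se_reduction) if se_reduction else Identity()
        self.down = (
            _conv_bn(in_ch, out_ch, 1, stride=stride, act=None)
            if stride != 1 or in_ch != out_ch
            else Identity()
        )
        self.relu = ReLU()

    def forward(self, x):
        y = self.se(self.conv3(self.conv2(self.conv1(x))))
        return self.relu(y + self.down(x))


class ResNetEncoder(Module):
    def __init__(self, block_counts, groups=1, base_width=64, se_reduction=0):
        super().__init__()
        self.stem = _conv_bn(3, 64, 7, stride=2)
        self.pool = MaxPool2d(3, 2, 1)
        stages = []
        in_ch = 64
        for si, n_blocks in enumerate(block_counts):
            out_ch = 256 * 2**si
            width = (base_width * 2**si) * groups // 64 if groups > 1 else 64 * 2**si
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (si > 0 and b == 0) else 1
                blocks.append(Bottleneck(in_ch, width, out_ch, stride, groups, se_reduction))
                in_ch = out_ch
            stages.append(Sequential(*blocks))
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self.tap_channels = [64, 256, 512, 1024, 2048]

    def forward(self, x):
        c1 = self.stem(x)
        c2 = self.stage1(self.pool(c1))
        c3 = self.stage2(c2)
        c4 = self.stage3(c3)
        c5 = self.stage4(c4)
        return [c1, c2, c3, c4, c5]


# -------------------------------------------------------------- DenseNet
class DenseLayer(Module):
    def __init__(self, in_ch, growth=32, bn_size=4):
        super().__init__()
        self.norm1 = BatchNorm2d(in_ch)
        self.relu = ReLU()
        self.conv1 = Conv2d(in_ch, bn_size * growth, 1, bias=False)
        self.norm2 = BatchNorm2d(bn_size * growth)
        self.conv2 = Conv2d(bn_size * growth, growth, 3, bias=False)

    def forward(self, x):
        y = self.conv1(self.relu(self.norm1(x)))
        y = self.conv2(self.relu(self.norm2(y)))
        return ag.concat([x, y], axis=1)


class DenseNetEncoder(Module):
    def __init__(self, block_counts=(6, 12, 32, 32), growth=32):
        super().__init__()
        self.stem = _conv_bn(3, 64, 7, stride=2)
        self.pool = MaxPool2d(3, 2, 1)
        ch = 64
        taps = [64]
        for bi, n_layers in enumerate(block_counts):
            layers = []
            for _ in range(n_layers):
                layers.append(DenseLayer(ch, growth))
                ch += growth
            setattr(self, f"block{bi + 1}", Sequential(*layers))
            if bi < len(block_counts) - 1:
                setattr(
                    self,
                    f"trans{bi + 1}",
                    Sequential(BatchNorm2d(ch), ReLU(), Conv2d(ch, ch // 2, 1, bias=False)),
                )
                ch //= 2
                taps.append(ch)
        self.final_norm = BatchNorm2d(ch)
        self.final_relu = ReLU()
        self.tap_channels = taps + [ch]

    def forward(self, x):
        c1 = self.stem(x)
        y = self.pool(c1)
        taps = [c1]
        for bi in range(1, 5):
            y = getattr(self, f"block{bi}")(y)
            if bi < 4:
                y = getattr(self, f"trans{bi}")(y)
                taps.append(y)  # compressed transition output, pre-pool
                y = ag.avgpool2d(y, 2, 2)
        taps.append(self.final_relu(self.final_norm(y)))
        return taps


# ----------------------------------------------------------- EfficientNet
def _round_filters(f: int, mult: float) -> int:
    f *= mult
    new = max(8, int(f + 4) // 8 * 8)
    if new < 0.9 * f:
        new += 8
    return int(new)


def _round_repeats(r: int, mult: float) -> int:
    return int(math.ceil(r * mult))


class MBConv(Module):
    """Mobile inverted bottleneck with squeeze-excitation."""

    def __init__(self, in_ch, out_ch, expand, kernel, stride):
        super().__init__()
        mid = in_ch * expand
        self.expand = _conv_bn(in_ch, mid, 1, act=SiLU) if expand != 1 else Identity()
        self.depthwise = _conv_bn(mid, mid, kernel, stride=stride, groups=mid, act=SiLU)
        self.se = SqueezeExcite(mid, max(1, in_ch // 4), act=SiLU)
        self.project = _conv_bn(mid, out_ch, 1, act=None)
        self.residual = stride == 1 and in_ch == out_ch

    def forward(self, x, return_expand: bool = False):
        e = self.expand(x)
        y = self.project(self.se(self.depthwise(e)))
        if self.residual:
            y = y + x
        return (y, e) if return_expand else y


_EFFNET_BASE = [  # (expand, channels, repeats, stride, kernel) for B0
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
]
_EFFNET_SCALE = {"b3": (1.2, 1.4), "b4": (1.4, 1.8)}


class EfficientNetEncoder(Module):
    def __init__(self, variant: str = "b4"):
        super().__init__()
        w, d = _EFFNET_SCALE[variant]
        stem_ch = _round_filters(32, w)
        self.stem = _conv_bn(3, stem_ch, 3, stride=2, act=SiLU)
        in_ch = stem_ch
        self.stages = []
        tap_channels = [0, 0, 0, 0]
        tap_i = 0
        for expand, ch, repeats, stride, kernel in _EFFNET_BASE:
            out_ch = _round_filters(ch, w)
            blocks = []
            for b in range(_round_repeats(repeats, d)):
                blocks.append(MBConv(in_ch, out_ch, expand, kernel, stride if b == 0 else 1))
                in_ch = out_ch
            if stride == 2:
                tap_channels[tap_i] = blocks[0].expand.mods[1].weight.data.size  # BN channels
                tap_i += 1
            self.stages.append(blocks)
        for i, blocks in enumerate(self.stages):
            setattr(self, f"stage{i + 1}", Sequential(*blocks))
        head_ch = _round_filters(1280, w)
        self.head = _conv_bn(in_ch, head_ch, 1, act=SiLU)
        # expand taps sit before their stride-2 depthwise conv, so the tap
        # resolutions are 1/2, 1/4, 1/8, 1/16 and the head is the 1/32 bottleneck
        self.tap_channels = tap_channels + [head_ch]

    def forward(self, x):
        y = self.stem(x)
        taps = []
        for expand_cfg, blocks in zip(_EFFNET_BASE, self.stages):
            for b, block in enumerate(blocks):
                if b == 0 and expand_cfg[3] == 2:
                    y, e = block(y, return_expand=True)
                    taps.append(e)
                else:
                    y = block(y)
        taps.append(self.head(y))
        return taps


# ------------------------------------------------------------------ tiny
class TinyEncoder(Module):
    """Five stride-2 conv-BN-ReLU stages; small enough to train on CPU."""

    def __init__(self, channels=(12, 16, 24, 32, 48)):
        super().__init__()
        in_ch = 3
        for i, ch in enumerate(channels):
            setattr(self, f"stage{i + 1}", _conv_bn(in_ch, ch, 3, stride=2))
            in_ch = ch
        self.tap_channels = list(channels)

    def forward(self, x):
        taps = []
        for i in range(5):
            x = getattr(self, f"stage{i + 1}")(x)
            taps.append(x)
        return taps


ENCODERS = {
    "resnet50": lambda: ResNetEncoder((3, 4, 6, 3)),
    "densenet169": lambda: DenseNetEncoder((6, 12, 32, 32)),
    "se_resnext50": lambda: ResNetEncoder((3, 4, 6, 3), groups=32, base_width=4 * 64, se_reduction=16),
    "se_resnext101": lambda: ResNetEncoder((3, 4, 23, 3), groups=32, base_width=4 * 64, se_reduction=16),
    "efficientnet_b4": lambda: EfficientNetEncoder("b4"),
    "efficientnet_b3": lambda: EfficientNetEncoder("b3"),
    "tiny": lambda: TinyEncoder(),
}


def build_encoder(name: str) -> Module:
    try:
        return ENCODERS[name]()
    except KeyError:
        raise ValueError(f"unsupported backbone {name!r}; choose from {sorted(ENCODERS)}") from None
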