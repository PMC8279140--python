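"""Backbone U-Net construction.

A B-UNet is an ImageNet-style encoder truncated before pooling/classifier,
plus a five-block decoder.  Decoder blocks 1-4 do: nearest-neighbor 2x
upsample -> concatenate the matching encoder tap -> two 3x3 conv(+BN)+ReLU;
block 5 has no skip.  Decoder channels halve 256 -> 16 in the full presets.
A 3x3 convolution to one channel plus a sigmoid yields the per-pixel
probability map at input resolution (input sides must be divisible by 32).
DenseNet169-UNet omits decoder batch normalization, as in the reference
configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .backbones import ENCODERS, build_encoder
from .nn import Conv2d, Module, ReLU, Sequential, Sigmoid, Tensor, UpsampleNearest2x, no_grad
from .nn.layers import BatchNorm2d
from .nn import autograd as ag

__all__ = [
    "ArchitectureSpec",
    "BUNet",
    "PRESETS",
    "build_bunet",
    "count_parameters",
    "flip_equivariance_probe",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ArchitectureSpec:
    """Declarative description of one backbone U-Net."""

    backbone: str
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)
    decoder_batchnorm: bool = True
    pretrained: bool = False
    weights_path: str | None = None
    input_channels: int = 3

    def __post_init__(self):
        if len(self.decoder_channels) != 5:
            raise ValueError("decoder_channels must list five block widths")
        if self.backbone not in ENCODERS:
            raise ValueError(f"unsupported backbone {self.backbone!r}; choose from {sorted(ENCODERS)}")


# the four reference configurations, plus the optional extra backbones and
# a small preset for CPU-scale training runs
PRESETS: dict[str, ArchitectureSpec] = {
    "resnet50_unet": ArchitectureSpec("resnet50"),
    "densenet169_unet": ArchitectureSpec("densenet169", decoder_batchnorm=False),
    "se_resnext50_unet": ArchitectureSpec("se_resnext50"),
    "efficientnetb4_unet": ArchitectureSpec("efficientnet_b4"),
    "se_resnext101_unet": ArchitectureSpec("se_resnext101"),
    "efficientnetb3_unet": ArchitectureSpec("efficientnet_b3"),
    "tiny_unet": ArchitectureSpec("tiny", decoder_channels=(32, 24, 16, 12, 8)),
}


class DecoderBlock(Module):
    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, batchnorm: bool):
        super().__init__()
        self.up = UpsampleNearest2x()
        convs: list[Module] = []
        c = in_ch + skip_ch
        for _ in range(2):
            convs.append(Conv2d(c, out_ch, 3, bias=not batchnorm))
            if batchnorm:
                convs.append(BatchNorm2d(out_ch))
            convs.append(ReLU())
            c = out_ch
        self.convs = Sequential(*convs)
        self.has_skip = skip_ch > 0

    def forward(self, x, skip=None):
        x = self.up(x)
        if self.has_skip:
            x = ag.concat([x, skip], axis=1)
        return self.convs(x)


class BUNet(Module):
    """Encoder-decoder segmentation network with a sigmoid pixel head."""

    def __init__(self, spec: ArchitectureSpec):
        super().__init__()
        self.spec = spec
        self.encoder = build_encoder(spec.backbone)
        taps = self.encoder.tap_channels  # strides [2, 4, 8, 16, 32]
        skips = [taps[3], taps[2], taps[1], taps[0], 0]  # deep -> shallow, none for block 5
        in_ch = taps[4]
        blocks = []
        for out_ch, skip_ch in zip(spec.decoder_channels, skips):
            blocks.append(DecoderBlock(in_ch, skip_ch, out_ch, spec.decoder_batchnorm))
            in_ch = out_ch
        self.decoder = Sequential(*blocks)
        self.head = Sequential(Conv2d(spec.decoder_channels[-1], 1, 3), Sigmoid())

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 32")
        taps = self.encoder(x)
        y = taps[4]
        skips = [taps[3], taps[2], taps[1], taps[0], None]
        for block, skip in zip(self.decoder, skips):
            y = block(y, skip)
        return self.head(y)

    @property
    def parameter_count(self) -> int:
        return self.num_parameters()

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map (H, W) in [0, 1] for one (H, W, 3) image in [0, 1]."""
        x = np.transpose(np.asarray(image, dtype=np.float32), (2, 0, 1))[None]
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(Tensor(x))
        finally:
            self.train(was_training)
        return out.data[0, 0].astype(np.float64)


def build_bunet(spec: ArchitectureSpec | str, seed: int = 0) -> BUNet:
    """Build (and randomly initialize) a B-UNet from a spec or preset name.

    With ``spec.pretrained`` set, weights are loaded from
    ``spec.weights_path`` (a checkpoint produced by :func:`save_checkpoint`)
    instead; no download is ever attempted.
    """
    if isinstance(spec, str):
        try:
            spec = PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown preset {spec!r}; choose from {sorted(PRESETS)}") from None
    net = BUNet(spec)
    net.initialize(np.random.default_rng(seed))
    if spec.pretrained:
        if not spec.weights_path:
            raise ValueError("pretrained=True requires weights_path")
        net.load_state_dict(_read_state(spec.weights_path))
    return net


def count_parameters(net: Module) -> int:
    """Total trainable parameter count (BN running stats excluded)."""
    return net.num_parameters()


def flip_equivariance_probe(net: BUNet, image: np.ndarray) -> float:
    """Mean |unflip(f(flip(x))) - f(x)|: how far the net is from horizontal
    flip equivariance.  Zero for symmetric inputs or constant heads."""
    p = net.predict(image)
    p_flip = net.predict(image[:, ::-1, :])[:, ::-1]
    return float(np.mean(np.abs(p_flip - p)))


def save_checkpoint(net: BUNet, path) -> None:
    """Weights plus the architecture spec in one .npz file."""
    state = net.state_dict()
    state["__spec__"] = np.frombuffer(
        json.dumps(asdict(net.spec)).encode(), dtype=np.uint8
    ).copy()
    np.savez_compressed(path, **state)


def _read_state(path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files if k != "__spec__"}


def load_checkpoint(path) -> BUNet:
    path = Path(path)
    with np.load(path) as z:
        spec_dict = json.loads(bytes(z["__spec__"]).decode())
        state = {k: z[k] for k in z.files if k != "__spec__"}
    spec_dict["decoder_channels"] = tuple(spec_dict["decoder_channels"])
    spec_dict.update(pretrained=False, weights_path=None)
    net = BUNet(ArchitectureSpec(**spec_dict))
    net.load_state_dict(state)
    return net
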