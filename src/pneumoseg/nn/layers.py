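"""Neural network modules over the autograd engine (NCHW layout)."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module", "Sequential", "Identity", "Conv2d", "BatchNorm2d",
    "ReLU", "SiLU", "Sigmoid", "MaxPool2d", "AvgPool2d",
    "GlobalAvgPool", "UpsampleNearest2x",
]


class Module:
    """Base class: parameter/buffer registration, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            yield from mod.named_modules(f"{prefix}.{name}" if prefix else name)

    def named_parameters(self):
        for prefix, mod in self.named_modules():
            for name, p in mod._params.items():
                yield (f"{prefix}.{name}" if prefix else name), p

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for _, mod in self.named_modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, mod in self.named_modules():
            for name, p in mod._params.items():
                out[f"{prefix}.{name}" if prefix else name] = p.data.copy()
            for name, b in mod._buffers.items():
                out[f"{prefix}.{name}" if prefix else name] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_buffers = {}
        for prefix, mod in self.named_modules():
            for name in mod._buffers:
                own_buffers[f"{prefix}.{name}" if prefix else name] = (mod, name)
        expected = set(own_params) | set(own_buffers)
        if expected != set(state):
            missing = sorted(expected - set(state))[:5]
            extra = sorted(set(state) - expected)[:5]
            raise ValueError(f"state dict mismatch; missing {missing}, unexpected {extra}")
        for key, value in state.items():
            if key in own_params:
                p = own_params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: {p.data.shape} vs {value.shape}")
                p.data = np.asarray(value, dtype=np.float32).copy()
            else:
                mod, name = own_buffers[key]
                mod._set_buffer(name, value.copy())

    def initialize(self, rng: np.random.Generator) -> "Module":
        """He-normal conv weights, zero biases, unit BN scale; deterministic
        in the (stable) module registration order."""
        for _, mod in self.named_modules():
            if isinstance(mod, Conv2d):
                fan_in = mod.weight.data[0].size
                mod.weight.data = rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), mod.weight.data.shape
                ).astype(np.float32)
                if mod.bias is not None:
                    mod.bias.data = np.zeros_like(mod.bias.data)
            elif isinstance(mod, BatchNorm2d):
                mod.reset()
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding="same", groups=1, bias=True):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"channels ({in_ch}->{out_ch}) not divisible by groups={groups}")
        self.stride = stride
        self.groups = groups
        self.padding = kernel // 2 if padding == "same" else padding
        self.register_parameter("weight", np.zeros((out_ch, in_ch // groups, kernel, kernel), dtype=np.float32))
        self.bias = None
        if bias:
            self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    """Batch normalization with running statistics.

    ``momentum=None`` switches the running-stat update to a cumulative
    average, which is what the post-averaging statistics refresh uses.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float | None = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.register_parameter("weight", np.ones(channels, dtype=np.float32))
        self.register_parameter("bias", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.register_buffer("num_batches", np.zeros(1, dtype=np.float32))

    def reset(self) -> None:
        self.weight.data = np.ones_like(self.weight.data)
        self.bias.data = np.zeros_like(self.bias.data)
        self.reset_running_stats()

    def reset_running_stats(self) -> None:
        self._set_buffer("running_mean", np.zeros_like(self.running_mean))
        self._set_buffer("running_var", np.ones_like(self.running_var))
        self._set_buffer("num_batches", np.zeros(1, dtype=np.float32))

    def forward(self, x):
        c = self.weight.data.size
        shape = (1, c, 1, 1)
        if self.training:
            mean = ag.tmean(x, axes=(0, 2, 3), keepdims=True)
            var = ag.tmean((x - mean) ** 2.0, axes=(0, 2, 3), keepdims=True)
            m = float(self.num_batches[0])
            w = 1.0 / (m + 1.0) if self.momentum is None else self.momentum
            self._set_buffer(
                "running_mean", (1 - w) * self.running_mean + w * mean.data.reshape(c)
            )
            self._set_buffer(
                "running_var", (1 - w) * self.running_var + w * var.data.reshape(c)
            )
            self._set_buffer("num_batches", np.asarray([m + 1.0], dtype=np.float32))
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * _reshape_param(self.weight, shape) + _reshape_param(self.bias, shape)


def _reshape_param(p: Tensor, shape) -> Tensor:
    """View a 1-D parameter as (1, C, 1, 1) while keeping it on the tape."""
    out = Tensor(p.data.reshape(shape))
    if p.requires_grad and ag._grad_enabled:
        out.requires_grad = True
        out._prev = (p,)

        def backward(g, p=p, c=p.data.size):
            ag._accum(p, g.reshape(c))

        out._backward = backward
    return out


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class SiLU(Module):
    def forward(self, x):
        return ag.silu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel=2, stride=None, padding=0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, padding

    def forward(self, x):
        return ag.maxpool2d(x, self.kernel, self.stride, self.pad)


class AvgPool2d(Module):
    def __init__(self, kernel=2, stride=None):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x):
        return ag.avgpool2d(x, self.kernel, self.stride)


class GlobalAvgPool(Module):
    def forward(self, x):
        return ag.tmean(x, axes=(2, 3), keepdims=True)


class UpsampleNearest2x(Module):
    def forward(self, x):
        return ag.upsample_nearest2x(x)
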