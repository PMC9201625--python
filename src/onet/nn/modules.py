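"""Layer abstractions over the autodiff engine.

Mirrors the familiar ``Module`` idiom: layers own parameter tensors,
submodules are discovered from attributes, and ``named_parameters`` yields
dotted names usable for checkpointing and scoped parameter counts.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import (Tensor, conv2d, conv_transpose2x2, erf, relu, sigmoid)

_default_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the global parameter-initialisation stream."""
    global _default_rng
    _default_rng = np.random.default_rng(seed)


def _rng(rng):
    return rng if rng is not None else _default_rng


class Parameter(Tensor):
    """A tensor registered as trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal_(shape, std: float = 0.02, rng=None) -> Parameter:
    r = _rng(rng)
    vals = r.normal(0.0, std, size=shape)
    return Parameter(np.clip(vals, -2 * std, 2 * std))


def kaiming_normal_(shape, fan_in: int, rng=None) -> Parameter:
    r = _rng(rng)
    return Parameter(r.normal(0.0, math.sqrt(2.0 / fan_in), size=shape))


class Module:
    def __init__(self):
        self.training = True

    # attribute scan keeps registration implicit, like the big frameworks
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in self.__dict__.items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def _own_params(self) -> Iterator[tuple[str, Parameter]]:
        for name, val in self.__dict__.items():
            if isinstance(val, Parameter):
                yield name, val

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._own_params():
            yield prefix + name, p
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):  # set by subclasses
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, val in state.items():
            if key in own:
                if own[key].data.shape != val.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{own[key].data.shape} vs {val.shape}")
                own[key].data = np.asarray(val, dtype=np.float64).copy()
            elif key in bufs:
                self._set_buffer(key, val)
            else:
                raise KeyError(f"unexpected parameter {key!r} in state dict")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)[:3]} ...")

    def _set_buffer(self, dotted: str, val: np.ndarray) -> None:
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if isinstance(obj, ModuleList) else obj.__dict__[part]
        setattr(obj, parts[-1], np.asarray(val, dtype=np.float64).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    """Plain list of modules that participates in parameter discovery."""


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, rng=None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = trunc_normal_((in_features, out_features), rng=rng)
        if bias:
            self.bias = Parameter(np.zeros(out_features))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def _own_params(self):
        yield "weight", self.weight
        if self.bias is not None:
            yield "bias", self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, groups: int = 1, bias: bool = True, rng=None):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kh * kw
        self.weight = kaiming_normal_((out_channels, in_channels // groups, kh, kw),
                                      fan_in, rng=rng)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)

    def _own_params(self):
        yield "weight", self.weight
        if self.bias is not None:
            yield "bias", self.bias


class ConvTranspose2x2(Module):
    """Learnable 2x upsampling (transposed conv, kernel 2, stride 2)."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True, rng=None):
        super().__init__()
        self.weight = kaiming_normal_((in_channels, out_channels, 2, 2),
                                      in_channels * 4, rng=rng)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)

    def _own_params(self):
        yield "weight", self.weight
        if self.bias is not None:
            yield "bias", self.bias


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1) * unbias)
            xhat = xc / (var + self.eps) ** 0.5
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xhat = (x - mu) / sd
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class LayerNorm(Module):
    """Normalisation over the last axis (token channels)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps) ** 0.5
        return xhat * self.weight + self.bias


class GELU(Module):
    """Exact (erf-form) Gaussian error linear unit."""

    def forward(self, x: Tensor) -> Tensor:
        return x * 0.5 * (erf(x * (1.0 / math.sqrt(2.0))) + 1.0)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class SiLU(Module):
    """Swish / sigmoid-weighted linear unit."""

    def forward(self, x: Tensor) -> Tensor:
        return x * sigmoid(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return sigmoid(x)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))
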