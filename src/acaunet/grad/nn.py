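"""Neural-network layers on top of the :mod:`acaunet.grad.tensor` engine.

Layers follow the familiar Module pattern: parameters and sub-modules assigned
as attributes are discovered automatically, ``state_dict`` round-trips through
plain dicts of arrays, and ``train()``/``eval()`` toggle batch-norm behaviour.

Weight initialisation is Kaiming fan-in (normal), appropriate for the
ReLU-dominated blocks used here; every constructor draws from an explicit
``numpy.random.Generator`` so two builds from the same seed produce identical
parameter vectors.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Identity",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "BatchNorm2d",
    "InstanceNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "AvgPool2d",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------ state dict
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_buffers():
            state[name] = m.copy()
        return state

    def _named_buffers(self, prefix: str = ""):
        for name, m in self._modules.items():
            yield from m._named_buffers(prefix + name + ".")
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: None for name, _ in self._named_buffers()}
        for key, value in state.items():
            if key in params:
                if params[key].shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.asarray(value, dtype=np.float32).copy()
            elif key in buffers:
                self._set_buffer(key, value)
            else:
                raise KeyError(f"unexpected key {key!r} in state dict")

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        obj: Module = self
        for part in parts[:-1]:
            obj = obj._modules[part]
        object.__setattr__(obj, parts[-1], np.asarray(value, dtype=np.float32).copy())

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, str(i), layer)
        self._layers = layers

    def forward(self, x: Tensor) -> Tensor:
        for layer in self._layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 *, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming(rng, (in_channels, out_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 *, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose()
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel normalisation over (batch, H, W) with running statistics.

    With batch size 1 — the training default here — this behaves like
    instance normalisation during training while evaluation uses the
    exponentially averaged statistics.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        object.__setattr__(self, "running_mean", np.zeros(channels, dtype=np.float32))
        object.__setattr__(self, "running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean += m * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += m * (var.data.reshape(-1) - self.running_var)
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            sd = Tensor(np.sqrt(self.running_var + self.eps).reshape(shape))
            xhat = (x - mu) / sd
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over (H, W) with affine scale/shift.

    Statistics come from the current input in both training and evaluation,
    so the two modes are identical and batch elements never interact — the
    natural choice for a batch-size-1 training protocol.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1)
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size: int):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return F.avg_pool2d(x, self.kernel_size)
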