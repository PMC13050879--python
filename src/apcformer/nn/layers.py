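"""Neural-network layers over the autograd engine.

Parameters are float32 by default.  Layers follow the usual conventions:
``BatchNorm2d`` normalizes over (batch, height, width) with running
statistics for eval mode, ``Dropout`` uses inverted scaling, and weight
initialization is Glorot-uniform for dense/conv weights.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, avg_pool2d, conv2d


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(full)
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def modules(self) -> Iterator["Module"]:
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(attr, Module):
                yield from attr.named_buffers(full)
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}")
            elif isinstance(attr, np.ndarray) and name.startswith("running_"):
                yield full, attr

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (owner, attr) for owner, name, attr
                   in self._buffer_owners()}
        for key, value in state.items():
            if key in params:
                params[key].data = np.array(value, dtype=params[key].dtype)
            elif key in buffers:
                owner, attr = buffers[key]
                setattr(owner, attr, np.array(value))
            else:
                raise KeyError(f"unexpected state entry {key!r}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")

    def _buffer_owners(self, prefix: str = ""):
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(attr, Module):
                yield from attr._buffer_owners(full)
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item._buffer_owners(f"{full}.{i}")
            elif isinstance(attr, np.ndarray) and name.startswith("running_"):
                yield self, full, name

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot_uniform(
            rng, (in_features, out_features), in_features, out_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """Stride-1 2-D convolution with optional grouping and 'same' padding."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int], rng: np.random.Generator,
                 groups: int = 1, bias: bool = True,
                 padding: str | tuple[int, int] = (0, 0)):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        kh, kw = kernel_size
        cg = in_channels // groups
        fan_in = cg * kh * kw
        fan_out = (out_channels // groups) * kh * kw
        self.weight = Parameter(glorot_uniform(
            rng, (out_channels, cg, kh, kw), fan_in, fan_out))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        if padding == "same":
            if kh % 2 == 0 or kw % 2 == 0:
                raise ValueError("'same' padding needs odd kernel sizes")
            padding = ((kh - 1) // 2, (kw - 1) // 2)
        self.padding = tuple(padding)
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            ).astype(np.float32)
            inv = (var + self.eps) ** (-0.5)
            xhat = centered * inv
        else:
            mu = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - mu) * inv[None, :, None, None]
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** (-0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        return x * (keep / (1.0 - self.p))


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.elu(self.alpha)


class AvgPool2d(Module):
    def __init__(self, kernel: tuple[int, int]):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.kernel)
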