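"""Parameterized layers and the module container used by the network."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Linear", "Conv2d", "LayerNorm", "InstanceNorm2d",
           "Sequential", "ReLU", "Upsample2x"]


class Module:
    """Tiny nn.Module analogue: named parameter registry + freezing."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _trainable(arr) -> Tensor:
    t = Tensor(arr)
    t.requires_grad = True
    return t


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return _trainable(rng.normal(0.0, scale, size=shape))


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int):
        super().__init__()
        self.weight = _param(rng, (in_dim, out_dim), (2.0 / in_dim) ** 0.5)
        self.bias = _param(rng, (out_dim,), 1e-6)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, rng, cin: int, cout: int, k: int = 3,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = k // 2
        fan_in = cin * k * k
        self.weight = _param(rng, (cout, cin, k, k), (2.0 / fan_in) ** 0.5)
        self.bias = _param(rng, (cout,), 1e-6)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    """Normalizes over the last axis (token features)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = _trainable(np.ones(dim))
        self.beta = _trainable(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class InstanceNorm2d(Module):
    """Per-channel spatial normalization of an NCHW map with affine
    parameters.  Preserves within-channel spatial contrast, which is what
    lets tiny bright structures survive a deep decoder."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = _trainable(np.ones((1, dim, 1, 1)))
        self.beta = _trainable(np.zeros((1, dim, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.upsample2x(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
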