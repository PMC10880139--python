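"""Parameter containers and neural-network building blocks."""

from __future__ import annotations

import numpy as np

from . import tensor as F
from .conv import conv2d, conv3d
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "Conv2d",
    "Conv3d",
    "Sequential",
    "trunc_normal",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, sd: float = 0.02) -> np.ndarray:
    """Normal(0, sd) samples truncated to +-2 sd (vision-transformer init)."""
    x = rng.normal(0.0, sd, size=shape)
    return np.clip(x, -2.0 * sd, 2.0 * sd)


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{full}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = np.asarray(state[name], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-k, k, size=(in_features, out_features)))
        self.bias = Parameter(rng.uniform(-k, k, size=(out_features,)))

    def __call__(self, x: Tensor) -> Tensor:
        return F.astensor(x) @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self._rng = np.random.default_rng(rng.integers(2**31))

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return F.astensor(x) * mask


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride, padding, rng: np.random.Generator):
        super().__init__()
        fan_in = cin * kernel * kernel
        k = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-k, k, size=(cout, cin, kernel, kernel)))
        self.bias = Parameter(rng.uniform(-k, k, size=(cout,)))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel, stride, padding, rng: np.random.Generator):
        super().__init__()
        fan_in = cin * kernel**3
        k = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-k, k, size=(cout, cin, kernel, kernel, kernel))
        )
        self.bias = Parameter(rng.uniform(-k, k, size=(cout,)))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x
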