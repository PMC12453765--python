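"""Neural-network building blocks on top of the autograd engine.

Layers follow the usual Module pattern: parameters are discovered by
recursing over attributes, ``state_dict``/``load_state_dict`` give a
value-exact checkpoint round trip, and ``train()``/``eval()`` switch
batch-norm and dropout behaviour.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d, maxpool2x2

__all__ = [
    "Module", "Linear", "Conv2d", "BatchNorm2d", "LayerNorm", "Dropout",
    "Sequential", "swish", "gelu", "relu", "sigmoid", "clipped_relu",
    "get_activation", "maxpool2x2",
]


# -- functional activations --------------------------------------------------

def swish(x: Tensor) -> Tensor:
    """x * sigmoid(x) (a.k.a. SiLU)."""
    return x * x.sigmoid()


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def clipped_relu(x: Tensor, ceiling: float = 6.0) -> Tensor:
    return x.relu().clip_max(ceiling)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, tanh approximation."""
    c = math.sqrt(2.0 / math.pi)
    inner = (x + 0.044715 * (x * x * x)) * c
    return 0.5 * (x * (1.0 + inner.tanh()))


_ACTIVATIONS = {
    "relu": relu,
    "sigmoid": sigmoid,
    "clipped relu": clipped_relu,
    "clipped_relu": clipped_relu,
    "swish": swish,
    "gelu": gelu,
}


def get_activation(name: str):
    key = name.strip().lower()
    if key not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}")
    return _ACTIVATIONS[key]


# -- module machinery ---------------------------------------------------------

class Module:
    def __init__(self):
        self.training = True

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and not v.requires_grad and name.startswith("running_"):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_buffers(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.data.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, t in own.items():
            arr = np.asarray(state[k])
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr.astype(t.data.dtype, copy=True)

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Module):
    """Affine map with Xavier-style init; `init_scale` shrinks it further
    (useful for classifier heads so training starts near-uniform)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float64, init_scale: float = 1.0):
        super().__init__()
        std = init_scale * math.sqrt(1.0 / in_features)
        self.weight = Tensor((rng.standard_normal((in_features, out_features)) * std
                              ).astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1, dtype=np.float64):
        super().__init__()
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Tensor(
            _he_init(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in, dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    """Batch normalisation over (B, H, W) per channel; eps 1e-5."""

    def __init__(self, num_features: int, dtype=np.float64, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = Tensor(np.zeros(num_features, dtype=dtype))
        self.running_var = Tensor(np.ones(num_features, dtype=dtype))
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        shape = (1, C, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            rdt = self.running_mean.data.dtype
            self.running_mean.data = ((1 - m) * self.running_mean.data
                                      + m * mu.data.reshape(C)).astype(rdt)
            self.running_var.data = ((1 - m) * self.running_var.data
                                     + m * var.data.reshape(C)).astype(rdt)
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean.data.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.data.reshape(shape) + self.eps)
            xhat = (x - mu) * inv
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float64, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
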