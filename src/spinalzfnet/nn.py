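"""Neural-network layers and optimizers built on :mod:`spinalzfnet.autodiff`.

Composite layers (batch norm, PReLU, local response normalisation, losses)
are expressed through the engine's primitives so their gradients follow from
the chain rule with no bespoke backward code.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module", "Linear", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "PReLU",
    "ReLU", "Dropout", "Dropout2d", "LocalResponseNorm", "Sequential",
    "cross_entropy", "softmax", "SGD", "RMSProp", "Adam", "he_init",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Minimal container: tracks parameters and sub-modules by attribute."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        params = list(self._params.values())
        for mod in self._modules.values():
            params.extend(mod.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for mname, mod in self._modules.items():
            out.extend(mod.named_parameters(prefix + mname + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(he_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride: int = 1, padding=0, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        fan_in = in_channels * kh * kw
        self.weight = Tensor(he_init(rng, (out_channels, in_channels, kh, kw), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, output_padding: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            he_init(rng, (in_channels, out_channels, kernel_size, kernel_size), fan_in),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=self.stride,
                                   padding=self.padding,
                                   output_padding=self.output_padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean).pow(2.0)).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
        else:
            mean = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mean) * (var + self.eps).pow(-0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class PReLU(Module):
    """relu(x) - a * relu(-x), slope learned per channel."""

    def __init__(self, num_channels: int, init: float = 0.25):
        super().__init__()
        self.slope = Tensor(np.full(num_channels, init), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
        return x.relu() - self.slope.reshape(shape) * (-x).relu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Element-wise dropout with inverted scaling at train time."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Dropout2d(Module):
    """Spatial dropout: whole feature maps are zeroed at train time."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random((x.shape[0], x.shape[1], 1, 1)) < keep) / keep
        return x * Tensor(mask)


class LocalResponseNorm(Module):
    """Across-channel response normalisation (the AlexNet/ZFNet scheme)."""

    def __init__(self, size: int = 5, alpha: float = 1e-4, beta: float = 0.75,
                 k: float = 2.0):
        super().__init__()
        self.size, self.alpha, self.beta, self.k = size, alpha, beta, k

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        half = self.size // 2
        sq = x.pow(2.0)
        zeros = Tensor(np.zeros((n, half, h, w)))
        padded = ad.concat([zeros, sq, zeros], axis=1)
        total = padded[:, 0:c]
        for off in range(1, self.size):
            total = total + padded[:, off:off + c]
        denom = (self.k + (self.alpha / self.size) * total).pow(self.beta)
        return x * denom.pow(-1.0)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``logits`` (N,K), ``labels`` int (N,)."""
    n, k = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant, no grad
    z = logits - shift
    lse = z.exp().sum(axis=1, keepdims=True).log() + shift
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    picked = (logits * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def _grad(self, p: Tensor) -> np.ndarray:
        if self.weight_decay:
            return p.grad + self.weight_decay * p.data
        return p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float = 0.01, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * self._grad(p)
            p.data = p.data + v


class RMSProp(Optimizer):
    def __init__(self, params, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.rho, self.eps = rho, eps
        self.sq = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            g = self._grad(p)
            s *= self.rho
            s += (1 - self.rho) * g ** 2
            p.data = p.data - self.lr * g / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = self._grad(p)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, params, lr: float,
                   weight_decay: float = 0.0) -> Optimizer:
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr, weight_decay=weight_decay)
    if name == "sgd":
        return SGD(params, lr=lr, momentum=0.9, weight_decay=weight_decay)
    if name == "rmsprop":
        return RMSProp(params, lr=lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}; expected Adam, SGD or RMSProp")
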