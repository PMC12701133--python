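"""Neural-network building blocks on top of :mod:`facesurv.autodiff`.

Thin torch-like layer: ``Module`` containers with recursive parameter
discovery, ``Conv2d``/``Linear``/``BatchNorm*`` layers, an Adam optimizer
and a finite-difference gradient checker used by the test suite.

All random initialisation takes an explicit ``numpy.random.Generator`` so a
fixed seed makes every construction (and therefore every training run)
bit-reproducible.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Module", "Sequential", "Conv2d", "Linear", "BatchNorm1d", "BatchNorm2d",
    "Adam", "gradient_check",
]


class Module:
    """Base class; parameters are ``Tensor``s with ``requires_grad=True``."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            mods.extend(_collect_modules(value))
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # checkpointing -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, (BatchNorm1d, BatchNorm2d)):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: Iterable[np.ndarray]):
        arrays = list(arrays)
        targets = self.state_arrays()
        if len(arrays) != len(targets):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(targets)}")
        for dst, src in zip(targets, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("checkpoint array shape mismatch")
            dst[...] = src

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    if isinstance(value, dict):
        out = []
        for v in value.values():
            out.extend(_collect(v))
        return out
    return []


def _collect_modules(value) -> list[Module]:
    if isinstance(value, Module):
        return value.modules()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    if isinstance(value, dict):
        out = []
        for v in value.values():
            out.extend(_collect_modules(v))
        return out
    return []


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class Relu(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    """3x3/1x1 convolution with He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale,
                       (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self.weight = Tensor(
            rng.uniform(-scale, scale, (in_features, out_features)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class _BatchNorm(Module):
    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def _normalize(self, x: Tensor, axes: tuple, shape: tuple) -> Tensor:
        if self.training:
            n = int(np.prod([x.shape[a] for a in axes]))
            if n <= 1:
                raise ValueError(
                    "batch normalization over a single element is undefined in "
                    "training mode; call .eval() for inference")
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) * n / max(n - 1, 1) - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self._g(shape) + self._b(shape)

    def _g(self, shape):
        return self.gamma.reshape(shape)

    def _b(self, shape):
        return self.beta.reshape(shape)


class BatchNorm1d(_BatchNorm):
    def forward(self, x):
        return self._normalize(x, (0,), (1, -1))


class BatchNorm2d(_BatchNorm):
    def forward(self, x):
        return self._normalize(x, (0, 2, 3), (1, -1, 1, 1))


class Adam:
    """Adam with bias correction; operates in-place on parameter data."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def gradient_check(loss_fn: Callable[[], Tensor], params: list[Tensor],
                   eps: float = 1e-5) -> float:
    """Max relative error between analytic and central-difference gradients.

    ``loss_fn`` must rebuild the graph on each call (parameters are perturbed
    in place between evaluations).
    """
    loss = loss_fn()
    for p in params:
        p.grad = None
    loss.backward()
    analytic = [p.grad.copy() if p.grad is not None else np.zeros_like(p.data)
                for p in params]
    worst = 0.0
    for p, ga in zip(params, analytic):
        flat = p.data.reshape(-1)
        gflat = ga.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_fn().item()
            flat[i] = orig - eps
            lm = loss_fn().item()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num), abs(gflat[i]), 1e-8)
            worst = max(worst, abs(num - gflat[i]) / denom)
    return worst
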