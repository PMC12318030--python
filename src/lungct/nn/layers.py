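"""Neural-network building blocks on top of the autograd engine.

Modules own :class:`Parameter` tensors and recursively expose them through
:meth:`Module.parameters`.  Weight initialisation is driven by an explicit
``numpy.random.Generator`` so that model construction is deterministic for a
given seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, conv2d, depthwise_conv2d)

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "DepthwiseSeparableConv2d",
    "Dense", "PReLU", "BatchNorm", "Dropout",
    "tensor_prelu", "tensor_d_silu", "softmax", "cross_entropy",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: child modules/parameters are discovered via __dict__."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, rng: np.random.Generator, in_channels: int,
                 out_channels: int, kernel_size: int, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = kernel_size // 2
        self.padding = padding
        fan_in = in_channels * kernel_size ** 2
        self.weight = Parameter(_he_init(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class DepthwiseSeparableConv2d(Module):
    """Depthwise k x k convolution followed by a pointwise 1 x 1 convolution.

    Parameter count is k^2*C + C*C' (+ biases) against k^2*C*C' for the full
    convolution with the same kernel and channels.
    """

    def __init__(self, rng: np.random.Generator, in_channels: int,
                 out_channels: int, kernel_size: int):
        super().__init__()
        self.padding = kernel_size // 2
        self.dw_weight = Parameter(_he_init(
            rng, (in_channels, kernel_size, kernel_size), kernel_size ** 2))
        self.dw_bias = Parameter(np.zeros(in_channels))
        self.pw_weight = Parameter(_he_init(
            rng, (out_channels, in_channels, 1, 1), in_channels))
        self.pw_bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        x = depthwise_conv2d(x, self.dw_weight, self.dw_bias, padding=self.padding)
        return conv2d(x, self.pw_weight, self.pw_bias, padding=0)


class Dense(Module):
    def __init__(self, rng: np.random.Generator, in_features: int, out_features: int):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class PReLU(Module):
    """Rectifier with one learnable negative slope per channel."""

    def __init__(self, channels: int, alpha_init: float = 0.25, channel_axis: int = 1):
        super().__init__()
        self.channel_axis = channel_axis
        self.alpha = Parameter(np.full(channels, alpha_init))

    def forward(self, x: Tensor) -> Tensor:
        shape = [1] * x.ndim
        shape[self.channel_axis] = -1
        alpha = self.alpha.reshape(*shape)
        pos = x.relu()
        return pos + alpha * (x - pos)


class BatchNorm(Module):
    """Normalise over all axes except the channel axis (NCHW layout)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(a for a in range(x.ndim) if a != 1)
        shape = [1] * x.ndim
        shape[1] = -1
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class Dropout(Module):
    """Inverted dropout; the mask stream is an explicit seeded generator."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


# -- tensor-valued activations shared by the networks ----------------------

def tensor_prelu(x: Tensor, alpha: Tensor) -> Tensor:
    pos = x.relu()
    return pos + alpha * (x - pos)


def tensor_d_silu(x: Tensor, variant: str = "improved_dsilu") -> Tensor:
    """Sigmoid-derivative-weighted linear unit on tensors.

    ``improved_dsilu`` gates the logistic through tanh (a bounded, dynamic
    scaling of the argument); ``conventional_dsilu`` uses the plain logistic.
    """
    if variant == "improved_dsilu":
        sf = x.tanh().sigmoid()
    elif variant == "conventional_dsilu":
        sf = x.sigmoid()
    else:
        raise ValueError(f"unknown d-SiLU variant: {variant!r}")
    return sf * (1.0 + x * (1.0 - sf))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))   # detached constant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits (stable log-sum-exp)."""
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    log_p = z - z.exp().sum(axis=-1, keepdims=True).log()
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(Tensor(onehot) * log_p).sum() * (1.0 / len(labels))
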