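"""Neural-network layers built on the autodiff engine.

Conventions: feature maps are NCHW, dense activations are (batch, features).
Weights are float64 and initialised He-style (suits the leaky-rectifier
activations used throughout). Every layer exposes ``parameters()`` for the
optimizer and ``state()``/``load_state()`` for flat-dict checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, col2im, im2col

__all__ = ["Module", "Linear", "Conv2d", "ConvTranspose2d", "BatchNorm",
           "LeakyReLU", "Sequential"]


class Module:
    def parameters(self) -> Iterator[Tensor]:
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def _children(self) -> Iterator["Module"]:
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> None:
        for m in self._children():
            m.train()

    def eval(self) -> None:
        for m in self._children():
            m.eval()

    # -- checkpointing -------------------------------------------------------
    def state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                out[key] = v.data.copy()
            elif isinstance(v, np.ndarray):
                out[key] = v.copy()
            elif isinstance(v, Module):
                out.update(v.state(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state(prefix=f"{key}.{i}."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = np.asarray(state[key], dtype=np.float64).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.asarray(state[key], dtype=np.float64).reshape(v.shape))
            elif isinstance(v, Module):
                v.load_state(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{i}.")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Tensor(_he(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Strided 2-D convolution via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, pad: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_channels * kernel * kernel
        self.weight = Tensor(_he(rng, (out_channels, fan_in), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def out_size(self, h: int) -> int:
        return (h + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        oh, ow = self.out_size(h), self.out_size(w)
        cols = im2col(x, self.kernel, self.stride, self.pad)     # (N, C*k*k, L)
        out = self.weight @ cols                                  # (N, Cout, L)
        out = out + self.bias.reshape(1, self.out_channels, 1)
        return out.reshape(n, self.out_channels, oh, ow)


class ConvTranspose2d(Module):
    """Transposed convolution (adjoint of the strided conv), via col2im."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, pad: int, output_pad: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.output_pad = output_pad
        fan_out_cols = out_channels * kernel * kernel
        self.weight = Tensor(_he(rng, (fan_out_cols, in_channels), in_channels),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.kernel + self.output_pad

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        oh, ow = self.out_size(h), self.out_size(w)
        flat = x.reshape(n, self.in_channels, h * w)
        cols = self.weight @ flat                                 # (N, Cout*k*k, H*W)
        out = col2im(cols, (oh, ow), self.out_channels, self.kernel,
                     self.stride, self.pad, (h, w))
        return out + self.bias.reshape(1, self.out_channels, 1, 1)


class BatchNorm(Module):
    """Batch normalization over batch (and spatial dims for NCHW inputs).

    The normalisation is composed from autodiff primitives, so its gradient
    comes for free; running statistics are tracked for evaluation mode.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.training = True

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 4:
            axes, shape = (0, 2, 3), (1, self.num_features, 1, 1)
        else:
            axes, shape = (0,), (1, self.num_features)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
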