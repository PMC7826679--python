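"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d, relu

__all__ = ["Module", "Conv2d", "ConvBNReLU", "BatchNorm2d", "Linear", "Sequential", "Identity"]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self) -> None:
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and not value.requires_grad:
                yield prefix + name, value.data
        for name, child in self._children():
            yield from child.buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buffers[key[len("buffer:") :]][...] = value
            else:
                params[key].data[...] = value


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int | tuple[int, int],
        stride: int | tuple[int, int] = 1,
        padding: int | tuple[int, int] = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        fan_in = in_channels * kh * kw
        self.weight = Tensor(
            _kaiming(rng, (out_channels, in_channels, kh, kw), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization with affine scale/shift.

    Batch statistics in training mode; exponential running averages (momentum
    0.1) at inference; epsilon 1e-5.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = Tensor(np.zeros(channels))
        self.running_var = Tensor(np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean.data[...] = (1 - m) * self.running_mean.data + m * mu.data.ravel()
            self.running_var.data[...] = (1 - m) * self.running_var.data + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.data.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.data.reshape(1, -1, 1, 1))
        x_hat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return x_hat * g + b


class ConvBNReLU(Module):
    """The conv → batch-norm/scale → ReLU unit used throughout the network."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int | tuple[int, int],
        stride: int | tuple[int, int] = 1,
        padding: int | tuple[int, int] = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.conv = Conv2d(
            in_channels, out_channels, kernel, stride=stride, padding=padding, bias=False, rng=rng
        )
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(
            _kaiming(rng, (in_features, out_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
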