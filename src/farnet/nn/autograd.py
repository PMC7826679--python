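"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and the
operations below build a computation graph whose ``backward`` pass accumulates
gradients by topological traversal.  Only the primitives the network needs are
provided (elementwise arithmetic, broadcasting-aware matmul, 2-D convolution
via im2col, pooling, reshapes, reductions and the usual activations).  All
arithmetic is float64 so finite-difference gradient checks are meaningful.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "avg_pool2d",
    "concat",
    "conv2d",
    "matmul",
    "max_pool2d",
    "relu",
    "sigmoid",
    "softplus",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(p for p in _parents if p.requires_grad)
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of a scalar (or supplied cotangent) output."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order by depth-first post-order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor(self.data / other.data, _parents=(self, other), _backward=backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, _parents=(self,), _backward=backward)

    def __matmul__(self, other) -> "Tensor":
        return matmul(self, other)

    def __getitem__(self, idx) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(self.data[idx], _parents=(self,), _backward=backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            g_exp = g if keepdims else np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g_exp, self.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            _parents=(self,),
            _backward=backward,
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ------------------------------------------------------------- activations
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, _parents=(x,), _backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable logistic

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, _parents=(x,), _backward=backward)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)) computed without overflow; d/dx = sigmoid(x)."""
    out_data = np.logaddexp(0.0, x.data)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * 0.5 * (1.0 + np.tanh(0.5 * x.data)))

    return Tensor(out_data, _parents=(x,), _backward=backward)


def matmul(a: Tensor, b) -> Tensor:
    """Matrix product with NumPy's stacked-batch broadcasting semantics."""
    a = as_tensor(a)
    b = as_tensor(b)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga.reshape(ga.shape), a.shape))
        if b.requires_grad:
            if a.data.ndim == 1:
                gb = np.multiply.outer(a.data, g)
            else:
                gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor(a.data @ b.data, _parents=(a, b), _backward=backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, stop)
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=backward,
    )


def _pair(v) -> tuple[int, int]:
    return (v, v) if np.isscalar(v) else tuple(v)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int | tuple[int, int] = 1,
    padding: int | tuple[int, int] = 0,
) -> Tensor:
    """2-D cross-correlation over NCHW input, weight (C_out, C_in, kh, kw)."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    n, c_in, h, w = x.shape
    c_out, c_in_w, kh, kw = weight.shape
    if c_in != c_in_w:
        raise ValueError(
            f"conv2d channel mismatch: input has {c_in} channels, weight expects {c_in_w}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    h_out = (h + 2 * ph - kh) // sh + 1
    w_out = (w + 2 * pw - kw) // sw + 1
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    # (n, h_out, w_out, c_in*kh*kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h_out * w_out, c_in * kh * kw)
    w_mat = weight.data.reshape(c_out, -1)
    out = cols @ w_mat.T
    if bias is not None:
        out = out + bias.data
    out = out.reshape(n, h_out, w_out, c_out).transpose(0, 3, 1, 2)

    def backward(g: np.ndarray) -> None:
        g_mat = g.transpose(0, 2, 3, 1).reshape(n * h_out * w_out, c_out)
        if weight.requires_grad:
            weight._accumulate((g_mat.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g_mat.sum(axis=0))
        if x.requires_grad:
            dcols = (g_mat @ w_mat).reshape(n, h_out, w_out, c_in, kh, kw)
            dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + sh * h_out : sh, j : j + sw * w_out : sw] += dcols[
                        :, :, :, :, i, j
                    ]
            x._accumulate(dxp[:, :, ph : ph + h, pw : pw + w])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, _parents=parents, _backward=backward)


def avg_pool2d(
    x: Tensor,
    kernel: int | tuple[int, int],
    stride: int | tuple[int, int],
    padding: int | tuple[int, int] = 0,
) -> Tensor:
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    h_out = (h + 2 * ph - kh) // sh + 1
    w_out = (w + 2 * pw - kw) // sw + 1
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    out = windows.mean(axis=(4, 5))

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        share = g / (kh * kw)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + sh * h_out : sh, j : j + sw * w_out : sw] += share
        x._accumulate(dxp[:, :, ph : ph + h, pw : pw + w])

    return Tensor(out, _parents=(x,), _backward=backward)


def max_pool2d(x: Tensor, kernel: int | tuple[int, int], stride: int | tuple[int, int]) -> Tensor:
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    n, c, h, w = x.shape
    h_out = (h - kh) // sh + 1
    w_out = (w - kw) // sw + 1
    windows = sliding_window_view(x.data, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    out = windows.max(axis=(4, 5))

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        # every window position attaining the max receives the gradient
        for i in range(kh):
            for j in range(kw):
                patch = x.data[:, :, i : i + sh * h_out : sh, j : j + sw * w_out : sw]
                mask = patch == out
                dx_view = dx[:, :, i : i + sh * h_out : sh, j : j + sw * w_out : sw]
                dx_view += g * mask
        x._accumulate(dx)

    return Tensor(out, _parents=(x,), _backward=backward)
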