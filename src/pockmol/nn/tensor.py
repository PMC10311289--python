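"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the encoder/decoder stacks need: broadcasted
arithmetic, (batched) matrix products, fancy-index gathers, reductions,
reshapes, concatenation and the elementwise nonlinearities. Gradients are
accumulated in float64 throughout.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        a, b = self.data, other.data

        def backward(g):
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b
                gb = np.tensordot(g, a, axes=(tuple(range(g.ndim)), tuple(range(g.ndim))))
            elif a.ndim == 1:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                ga = _unbroadcast(ga, a.shape)
                gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
                gb = _unbroadcast(gb, b.shape)
            else:
                ga = _unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)), a.shape)
                gb = _unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g), b.shape)
            return (ga, gb)

        return Tensor._make(out_data, (self, other), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- shape manipulation --------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._make(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            return (grad,)

        return Tensor._make(out_data, (self,), backward)

    def expand_dims(self, axis: int):
        return Tensor._make(
            np.expand_dims(self.data, axis), (self,), lambda g: (np.squeeze(g, axis),)
        )

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(data, requires_grad=True)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(out_data, tensors, backward)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        return (
            _unbroadcast(np.where(cond, g, 0.0), a.data.shape),
            _unbroadcast(np.where(cond, 0.0, g), b.data.shape),
        )

    return Tensor._make(out_data, (a, b), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - np.max(t.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - np.max(t.data, axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def masked_softmax(t: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax assigning exactly zero weight where `mask` is False."""
    mask = np.asarray(mask, dtype=bool)
    neg = np.where(mask, 0.0, -1e30)
    shifted = t + neg
    shifted = shifted - np.max(shifted.data, axis=axis, keepdims=True)
    e = shifted.exp() * mask.astype(np.float64)
    return e / e.sum(axis=axis, keepdims=True)


_DROPOUT_RNG: np.random.Generator | None = None


@contextlib.contextmanager
def dropout_mode(rng: np.random.Generator):
    """Enable stochastic dropout inside the block (training only)."""
    global _DROPOUT_RNG
    prev = _DROPOUT_RNG
    _DROPOUT_RNG = rng
    try:
        yield
    finally:
        _DROPOUT_RNG = prev


def maybe_dropout(t: Tensor, p: float) -> Tensor:
    """Inverted dropout; identity unless inside :func:`dropout_mode`."""
    if _DROPOUT_RNG is None or p <= 0.0:
        return t
    keep = (_DROPOUT_RNG.random(t.shape) >= p).astype(np.float64) / (1.0 - p)
    return t * keep


def layer_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = t.mean(axis=-1, keepdims=True)
    centered = t - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias
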