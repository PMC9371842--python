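"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operator set the transformer models in this
package need: broadcasting arithmetic, batched matmul, reductions, indexing /
gather, softmax, stable softplus/sigmoid, spatial 2x up/down-sampling and
cyclic rolls.  Gradients are accumulated in float64.  A graph is only built
while ``grad_enabled()`` is true; wrap inference in ``no_grad()``.

Backward closures receive the output gradient as an argument (they never
reference their own output tensor), so the graph is a plain DAG with no
reference cycles and is freed by reference counting as soon as the loss
goes out of scope.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to our reflected operators (ndarray <op> Tensor)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # _backward(grad) propagates the output gradient to the parents
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- properties -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- backward -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node is not self:
                    node.grad = None  # free intermediate gradients eagerly

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * b, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * a, other.shape))

        return Tensor._result(a * b, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / b, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * a / b**2, other.shape))

        return Tensor._result(a / b, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a = self.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * a ** (exponent - 1))

        return Tensor._result(a**exponent, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)),
                                         self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g),
                                          other.shape))

        return Tensor._result(np.matmul(a, b), (self, other), backward)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self):
        a = self.data

        def backward(g):
            if self.requires_grad:
                self._accum(g / a)

        return Tensor._result(np.log(a), (self,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._result(out_data, (self,), backward)

    def sigmoid(self):
        z = np.clip(self.data, -500, 500)
        out_data = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                            np.exp(z) / (1.0 + np.exp(z)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), backward)

    def softplus(self):
        x = self.data
        out_data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))

        def backward(g):
            if self.requires_grad:
                sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
                self._accum(g * sig)

        return Tensor._result(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        t = np.tanh(c * (x + 0.044715 * x**3))

        def backward(g):
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                self._accum(g * (0.5 * (1.0 + t)
                                 + 0.5 * x * (1.0 - t**2) * dinner))

        return Tensor._result(0.5 * x * (1.0 + t), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only inside the open interval."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        shape = self.shape

        def backward(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, shape).copy())

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims),
                              (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(in_shape))

        return Tensor._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._result(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        shape = self.shape
        dtype = self.data.dtype

        def backward(g):
            if self.requires_grad:
                full = np.zeros(shape, dtype=dtype)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._result(self.data[idx], (self,), backward)

    def roll(self, shift, axis):
        """Cyclic roll; exactly invertible, gradient rolls back."""

        def backward(g):
            if self.requires_grad:
                self._accum(np.roll(g, tuple(-s for s in np.atleast_1d(shift)),
                                    axis))

        return Tensor._result(np.roll(self.data, shift, axis), (self,), backward)

    def pad2d(self, pad_h: int, pad_w: int):
        """Zero-pad the two spatial axes of a (B, h, w, C) tensor on bottom/right."""
        widths = ((0, 0), (0, pad_h), (0, pad_w), (0, 0))
        h, w = self.shape[1], self.shape[2]

        def backward(g):
            if self.requires_grad:
                self._accum(g[:, :h, :w, :])

        return Tensor._result(np.pad(self.data, widths), (self,), backward)


# -- free functions -----------------------------------------------------------
def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    ndim = out_data.ndim

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(out_data, tensors, backward)


def maximum(a, b) -> Tensor:
    """Elementwise max; on ties the gradient goes to the first argument."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    take_a = a.data >= b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.shape))

    return Tensor._result(np.where(take_a, a.data, b.data), (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    take_a = a.data <= b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.shape))

    return Tensor._result(np.where(take_a, a.data, b.data), (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with the analytic Jacobian-vector backward."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (g - dot))

    return Tensor._result(out_data, (x,), backward)


def gather_tokens(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select per-batch token subsets: x (B, N, D), idx (B, K) -> (B, K, D)."""
    b = np.arange(x.shape[0])[:, None]
    shape = x.shape

    def backward(g):
        if x.requires_grad:
            full = np.zeros(shape)
            np.add.at(full, (b, idx), g)
            x._accum(full)

    return Tensor._result(x.data[b, idx], (x,), backward)


def scatter_tokens(x: Tensor, idx: np.ndarray, n_total: int, fill: Tensor) -> Tensor:
    """Place tokens x (B, K, D) at positions idx (B, K) in a (B, N, D) sequence
    whose remaining positions hold ``fill`` (broadcast (D,) vector)."""
    bsz, _, dim = x.shape
    b = np.arange(bsz)[:, None]
    out_data = np.broadcast_to(fill.data, (bsz, n_total, dim)).copy()
    out_data[b, idx] = x.data
    fill_shape = fill.shape

    def backward(g):
        if x.requires_grad:
            x._accum(g[b, idx])
        if fill.requires_grad:
            mask = np.ones((bsz, n_total), dtype=bool)
            mask[b, idx] = False
            fill._accum(g[mask].sum(axis=0).reshape(fill_shape))

    return Tensor._result(out_data, (x, fill), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of (B, h, w, C)."""
    b, h, w, c = x.shape

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(b, h, 2, w, 2, c).sum(axis=(2, 4)))

    return Tensor._result(x.data.repeat(2, axis=1).repeat(2, axis=2),
                          (x,), backward)


def avgpool2x(x: Tensor) -> Tensor:
    """2x2 average pooling of (B, h, w, C); h, w must be even."""
    b, h, w, c = x.shape
    out_data = x.data.reshape(b, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(g):
        if x.requires_grad:
            g4 = g[:, :, None, :, None, :] / 4.0
            g4 = np.broadcast_to(g4, (b, h // 2, 2, w // 2, 2, c))
            x._accum(g4.reshape(b, h, w, c))

    return Tensor._result(out_data, (x,), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._result(np.stack([t.data for t in tensors], axis=axis),
                          tensors, backward)


def parameters_zero_grad(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None
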