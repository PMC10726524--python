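"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's variational autoencoder is small enough (a few dense layers,
three 1-D convolutions per CDR3 chain) that a compact tape-based engine is
sufficient: every :class:`Tensor` records the operation that produced it and
`backward` walks the tape in reverse topological order accumulating
gradients.  Only the operations the model needs are implemented.

Convolutions use an im2col formulation (stride 1, same padding) so both the
forward and the backward pass reduce to matrix products.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

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
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents) if _GRAD_ENABLED else ()
        self._backward = _backward if _GRAD_ENABLED else None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------
    def _needs_tape(self, *others: "Tensor") -> bool:
        return _GRAD_ENABLED and (self.requires_grad or any(o.requires_grad for o in others))

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data
        if not self._needs_tape(other):
            return Tensor(out_data)
        out = Tensor(out_data, requires_grad=True, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data
        if not self._needs_tape(other):
            return Tensor(out_data)
        out = Tensor(out_data, requires_grad=True, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data
        if not self._needs_tape(other):
            return Tensor(out_data)
        out = Tensor(out_data, requires_grad=True, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)
        if not self._needs_tape():
            return Tensor(out_data)
        out = Tensor(out_data, requires_grad=True, _parents=(self,))
        mask = self.data > 0

        def _bw(g):
            self._accumulate(g * mask)

        out._backward = _bw
        return out

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        if not self._needs_tape():
            return Tensor(out_data)
        out = Tensor(out_data, requires_grad=True, _parents=(self,))

        def _bw(g):
            self._accumulate(g * out_data)

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)
        if not self._needs_tape():
            return Tensor(out_data)
        out = Tensor(out_data, requires_grad=True, _parents=(self,))

        def _bw(g):
            self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def square(self) -> "Tensor":
        return self * self

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not self._needs_tape():
            return Tensor(out_data)
        out = Tensor(out_data, requires_grad=True, _parents=(self,))
        orig = self.data.shape

        def _bw(g):
            self._accumulate(g.reshape(orig))

        out._backward = _bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self._needs_tape():
            return Tensor(out_data)
        out = Tensor(out_data, requires_grad=True, _parents=(self,))
        shape = self.data.shape

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy()
                                 if np.ndim(g) else np.full(shape, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis`, differentiably."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not (_GRAD_ENABLED and any(t.requires_grad for t in tensors)):
        return Tensor(out_data)
    out = Tensor(out_data, requires_grad=True, _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, L, C) -> (n, L, k*C) windows with same padding for stride-1 conv."""
    n, L, C = x.shape
    left = (k - 1) // 2
    right = k - 1 - left
    xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    # windows: (n, L, C, k) -> (n, L, k, C)
    return np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(n, L, k * C)


def _col2im(cols: np.ndarray, k: int, L: int, C: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add window gradients back to positions."""
    n = cols.shape[0]
    left = (k - 1) // 2
    right = k - 1 - left
    xg = np.zeros((n, L + k - 1, C))
    w = cols.reshape(n, L, k, C)
    for j in range(k):
        xg[:, j:j + L, :] += w[:, :, j, :]
    return xg[:, left:left + L, :] if right else xg[:, left:, :]


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1, same-padding 1-D convolution.

    x: (n, L, C_in); weight: (k, C_in, C_out); bias: (C_out,).
    Returns (n, L, C_out).
    """
    k, c_in, c_out = weight.data.shape
    n, L, cx = x.data.shape
    if cx != c_in:
        raise ValueError(f"conv1d channel mismatch: input {cx}, weight {c_in}")
    cols = _im2col(x.data, k)                      # (n, L, k*C_in)
    w2 = weight.data.reshape(k * c_in, c_out)
    out_data = cols @ w2 + bias.data
    if not (_GRAD_ENABLED and (x.requires_grad or weight.requires_grad
                               or bias.requires_grad)):
        return Tensor(out_data)
    out = Tensor(out_data, requires_grad=True, _parents=(x, weight, bias))

    def _bw(g):
        g2 = g.reshape(n * L, c_out)
        if weight.requires_grad:
            gw = cols.reshape(n * L, k * c_in).T @ g2
            weight._accumulate(gw.reshape(k, c_in, c_out))
        if bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ w2.T).reshape(n, L, k * c_in)
            x._accumulate(_col2im(gcols, k, L, c_in))

    out._backward = _bw
    return out


def softmax_cross_entropy(logits: Tensor, target_onehot: np.ndarray,
                          eps: float = 1e-8) -> Tensor:
    """Per-row cross-entropy -sum_c t_c log(softmax(logits)_c + eps).

    The class axis is the last one; the returned tensor has that axis
    reduced.  The backward pass uses the standard (p - t) form; the eps
    clamp only guards the forward log.
    """
    logits = Tensor.as_tensor(logits)
    t = np.asarray(target_onehot, dtype=np.float64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    out_data = -(t * np.log(p + eps)).sum(axis=-1)
    if not logits._needs_tape():
        return Tensor(out_data)
    out = Tensor(out_data, requires_grad=True, _parents=(logits,))

    def _bw(g):
        logits._accumulate(np.expand_dims(g, -1) * (p - t))

    out._backward = _bw
    return out
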