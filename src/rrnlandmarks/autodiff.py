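"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The relational reasoning network is small (tens of thousands of parameters,
batches of 64), so a lightweight tape-based engine is sufficient and keeps the
package free of heavyweight deep-learning dependencies.  Only the operations
the network actually uses are implemented: broadcast arithmetic, batched
matmul, ReLU, reductions, reshape/transpose/slice/concat and elementwise
exp/log/sqrt.  Arrays keep the caller's float precision (float32 or float64);
anything else is promoted to float64.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "numerical_gradient"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bwd=None):
        if isinstance(data, (np.ndarray, np.generic)) and \
                data.dtype in (np.float32, np.float64):
            self.data = np.asarray(data)  # keep caller's float precision
        else:
            self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._bwd = _bwd

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    def _accum(self, g: np.ndarray):
        # Rebinding (never in-place) lets gradients alias upstream buffers
        # safely and avoids a defensive copy on the common single-consumer path.
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            out = Tensor(self.data + other, _parents=(self,))

            def bwd_s(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))

            out._bwd = bwd_s
            return out
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._bwd = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        out._bwd = bwd
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            out = Tensor(self.data * other, _parents=(self,))

            def bwd_s(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other, self.data.shape))

            out._bwd = bwd_s
            return out
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._bwd = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._bwd = bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._bwd = bwd
        return out

    # -- elementwise nonlinearities -----------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._bwd = bwd
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * val)

        out._bwd = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._bwd = bwd
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._bwd = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            denom = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    # -- shape manipulation --------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._bwd = bwd
        return out

    def transpose(self, *perm):
        if len(perm) == 1 and isinstance(perm[0], (tuple, list)):
            perm = tuple(perm[0])
        out = Tensor(np.transpose(self.data, perm), _parents=(self,))
        inv = np.argsort(perm)

        def bwd(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        out._bwd = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx))

        def bwd(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                if basic:
                    buf[idx] += g
                else:
                    np.add.at(buf, idx, g)
                self._accum(buf)

        out._bwd = bwd
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accum(part)

    out._bwd = bwd
    return out


def numerical_gradient(fn, params: Iterable[Tensor], eps: float = 1e-6):
    """Central-difference gradients of scalar `fn()` w.r.t. each parameter.

    Used in the test suite as the independent oracle for the tape.
    """
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn().data)
            flat[i] = orig - eps
            lo = float(fn().data)
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads
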