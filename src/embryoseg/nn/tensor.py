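"""Minimal reverse-mode automatic differentiation over numpy arrays.

Scope is deliberately small: exactly the operations the segmentation
network needs (broadcast arithmetic, matmul, reductions, conv2d and
bilinear upsampling live in :mod:`embryoseg.nn.functional`).  Gradients
are accumulated in float32 and verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # keep numpy from hijacking arithmetic

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
                if parent._backward is None:
                    pass
        # leaves collected during traversal above; second pass for leaves
        # that still hold grads (those visited before their grad arrived
        # cannot happen in topo order, so nothing remains)
        for t in topo:
            if t._backward is None and id(t) in grads:
                g = grads.pop(id(t))
                t.grad = g if t.grad is None else t.grad + g

    # -- convenience ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out_data = self.data + other.data

        def bw(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = astensor(other)
        out_data = self.data * other.data

        def bw(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        return self * astensor(other) ** (-1.0)

    def __rtruediv__(self, other):
        return astensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            return (g * p * self.data ** (p - 1.0),)

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = astensor(other)
        out_data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a2 = a[None, :]
            else:
                a2 = a
            if b.ndim == 1:
                b2 = b[:, None]
                g2 = g[..., None]
            else:
                b2 = b
                g2 = g
            if a.ndim == 1:
                g2 = g2[..., None, :]
            ga = g2 @ np.swapaxes(b2, -1, -2)
            gb = np.swapaxes(a2, -1, -2) @ g2
            return (_unbroadcast(ga.reshape(ga.shape) if a.ndim > 1 else ga.reshape(a.shape + ()), a.shape)
                    if a.ndim > 1 else ga.reshape(a.shape),
                    _unbroadcast(gb, b.shape) if b.ndim > 1 else gb.reshape(b.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).astype(np.float32),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.data.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, self.data.shape).astype(np.float32),)

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.data.shape

        def bw(g):
            return (g.reshape(src_shape),)

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bw(g):
            return (g.transpose(inv),)

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        src_shape = self.data.shape

        def bw(g):
            full = np.zeros(src_shape, dtype=np.float32)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), bw)

    # -- pointwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return (g * out_data,)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            return (g / self.data,)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            return (g * (self.data > 0),)

        return Tensor._make(out_data, (self,), bw)

    def clamp(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            return (g * mask,)

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._make(out_data, (self,), bw)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bw)
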