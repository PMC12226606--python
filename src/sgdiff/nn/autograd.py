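"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's networks (latent codecs, graph encoders, the transformer
decoder and the diffusion denoisers) are small enough that a compact
tape-based engine over ``float64`` NumPy arrays is both fast enough on one
CPU and easy to verify: every primitive here is gradient-checked against
central finite differences in the test suite.

Only the primitives the package actually uses are implemented; there is no
attempt at a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "segment_sum", "segment_max", "no_grad"]


class _NoGrad:
    _active = False

    def __enter__(self):
        self.prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self.prev
        return False


def no_grad() -> _NoGrad:
    """Context manager disabling graph construction (evaluation mode)."""
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    """An array node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._backward = None
        self._parents: tuple = ()

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents) and not _NoGrad._active
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: [
                (a, _unbroadcast(g, a.shape)),
                (b, _unbroadcast(g, b.shape)),
            ]
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, -g)]
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: [
                (a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape)),
            ]
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: [
                (a, _unbroadcast(g / b.data, a.shape)),
                (b, _unbroadcast(-g * a.data / (b.data**2), b.shape)),
            ]
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g * p * a.data ** (p - 1))]
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            a, b = self, other

            def back(g):
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
                return [
                    (a, _unbroadcast(ga, a.shape)),
                    (b, _unbroadcast(gb, b.shape)),
                ]

            out._backward = back
        return out

    # -- elementwise nonlinearities -----------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = self._make(val, (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g * val)]
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g / a.data)]
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = self._make(val, (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g * 0.5 / val)]
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = self._make(val, (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g * (1.0 - val**2))]
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g * mask)]
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(val, (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g * val * (1.0 - val))]
        return out

    def gelu(self):
        # tanh approximation; exactness is irrelevant, smooth grads matter
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        val = 0.5 * x * (1.0 + t)
        out = self._make(val, (self,), None)
        if out.requires_grad:
            a = self

            def back(g):
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
                return [(a, g * d)]

            out._backward = back
        return out

    # -- reductions / shape -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            a = self

            def back(g):
                if axis is None:
                    return [(a, np.broadcast_to(g, a.shape).copy())]
                g2 = g if keepdims else np.expand_dims(g, axis)
                return [(a, np.broadcast_to(g2, a.shape).copy())]

            out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g.reshape(a.shape))]
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)
        if out.requires_grad:
            a = self
            out._backward = lambda g: [(a, g.transpose(inv))]
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)
        if out.requires_grad:
            a = self

            def back(g):
                ga = np.zeros_like(a.data)
                # integer fancy indices may repeat -> need unbuffered add
                parts = idx if isinstance(idx, tuple) else (idx,)
                fancy = any(isinstance(p, np.ndarray) and p.dtype != bool
                            for p in parts)
                if fancy:
                    np.add.at(ga, idx, g)
                else:
                    ga[idx] += g
                return [(a, ga)]

            out._backward = back
        return out

    # -- numerically stable composites --------------------------------
    def softmax(self, axis=-1):
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=-1, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = (self - Tensor(m)).exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            shifted = shifted.reshape(
                tuple(s for ax, s in enumerate(shifted.shape)
                      if ax != (axis % self.ndim))
            )
        return shifted

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors) and not _NoGrad._active
    out = Tensor(data, requires_grad=req)
    if req:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            parts = np.split(g, splits, axis=axis)
            return list(zip(tensors, parts))

        out._parents = tuple(tensors)
        out._backward = back
    return out


def segment_sum(src: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `src` (E×D) into `num_segments` buckets given by `index`.

    Empty segments yield zero rows — the "no in-neighbours → zero message"
    convention of the graph encoder relies on this.
    """
    src = _as_tensor(src)
    index = np.asarray(index, dtype=np.intp)
    data = np.zeros((num_segments,) + src.shape[1:], dtype=np.float64)
    np.add.at(data, index, src.data)
    out = Tensor(data, requires_grad=src.requires_grad and not _NoGrad._active)
    if out.requires_grad:
        out._parents = (src,)
        out._backward = lambda g: [(src, g[index])]
    return out


def segment_max(src: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment elementwise maximum; empty segments yield zeros.

    Gradient flows to the (first) argmax element per segment/column.
    """
    src = _as_tensor(src)
    index = np.asarray(index, dtype=np.intp)
    E, D = src.shape
    data = np.full((num_segments, D), -np.inf)
    np.maximum.at(data, index, src.data)
    empty = ~np.isfinite(data)
    data[empty] = 0.0
    out = Tensor(data, requires_grad=src.requires_grad and not _NoGrad._active)
    if out.requires_grad:
        # winner per (segment, col): first row achieving the max
        winner = np.full((num_segments, D), -1, dtype=np.intp)
        for e in range(E):
            s = index[e]
            hit = (src.data[e] == data[s]) & (winner[s] == -1)
            winner[s, hit] = e

        def back(g):
            gs = np.zeros_like(src.data)
            seg, col = np.nonzero(winner >= 0)
            gs[winner[seg, col], col] += g[seg, col]
            return [(src, gs)]

        out._parents = (src,)
        out._backward = back
    return out
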