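"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the recurrent networks, neural
ODEs and sequential autoencoders in this package: a :class:`Tensor` wraps
an ``ndarray``, records the operation that produced it, and ``backward``
walks the tape in reverse topological order accumulating gradients.
Broadcasting follows numpy rules; gradients of broadcast operands are
summed back to the operand's shape.

Only the operations the models need are implemented.  Everything is dense
float64 — the models here are small enough that simplicity beats speed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack", "split_steps", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference rollouts)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Sequence["Tensor"] = (), _backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._prev = tuple(_prev) if _grad_enabled else ()
        self._backward = _backward if _grad_enabled else None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.array(data, dtype=np.float64), requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative DFS: tapes from long rollouts overflow Python recursion
        stack_ = [(self, iter(self._prev))]
        seen.add(id(self))
        while stack_:
            node, it = stack_[-1]
            advanced = False
            for child in it:
                if id(child) not in seen and (child.requires_grad or child._prev):
                    seen.add(id(child))
                    stack_.append((child, iter(child._prev)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack_.pop()
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- ops ------------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, prev, backward) -> "Tensor":
        rg = any(p.requires_grad or p._prev for p in prev)
        out = Tensor(data, requires_grad=False, _prev=prev if rg else (),
                     _backward=backward if rg else None)
        out.requires_grad = False
        return out

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2,
                                      other.data.shape))

        return self._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.einsum("...k,...n->...kn", np.broadcast_to(a, b.shape[:-2] + a.shape), g) \
                    if b.ndim > 2 else np.outer(a, g)
            elif b.ndim == 1:
                ga = np.einsum("...m,k->...mk", g, b)
                gb = np.einsum("...mk,...m->k", a, g)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), bw)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return self._make(out_data, (self,), bw)

    @property
    def T(self):
        out_data = self.data.T

        def bw(g):
            self._accum(g.T)

        return self._make(out_data, (self,), bw)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = np.exp(-np.logaddexp(0.0, -self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), bw)

    def softplus(self):
        # numerically stable log(1+exp(x))
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            self._accum(g / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), bw)

    def clip_min(self, lo: float):
        out_data = np.maximum(self.data, lo)

        def bw(g):
            self._accum(g * (self.data >= lo))

        return self._make(out_data, (self,), bw)

    def clip_max(self, hi: float):
        out_data = np.minimum(self.data, hi)

        def bw(g):
            self._accum(g * (self.data <= hi))

        return self._make(out_data, (self,), bw)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(gpart)

    return tensors[0]._make(out_data, tuple(tensors), bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return tensors[0]._make(out_data, tuple(tensors), bw)


def split_steps(x: Tensor) -> list[Tensor]:
    """Split [B, T, K] into T views [B, K] with slice-wise backward.

    Cheaper than T ``__getitem__`` nodes: each child's gradient is added
    directly into the parent's gradient slice with no full-size
    temporary.
    """
    B, T, K = x.data.shape
    outs = []
    track = _grad_enabled and (x.requires_grad or x._prev)

    def make_bw(t):
        def bw(g):
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            x.grad[:, t] += g
        return bw

    for t in range(T):
        if track:
            out = Tensor(x.data[:, t], _prev=(x,), _backward=make_bw(t))
        else:
            out = Tensor(x.data[:, t])
        outs.append(out)
    return outs


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
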