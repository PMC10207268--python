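"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The gated-graph encoder-decoder in :mod:`fraglink.model` works on small,
irregular molecular graphs whose decoding traces change shape at every
step, so the training graph is rebuilt per example.  This module provides
exactly the tensor operations that network needs (matmul, gated-recurrent
nonlinearities, log-softmax reductions, row gather/concat) with a
micrograd-style tape, plus an Adam optimizer.

Gradient tracking can be suspended with :func:`no_grad` for pure sampling,
which reduces generation to plain NumPy arithmetic.
"""

from __future__ import annotations

import contextlib
from typing import Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables tape construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents if _GRAD_ENABLED else ()
        self._backward = backward if _GRAD_ENABLED else None
        self.requires_grad = requires_grad

    # -- helpers ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = (lambda g: self._accum(-g)) if _GRAD_ENABLED else None
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            else:
                self._accum(g @ b.T)
                other._accum(a.T @ g)

        out._backward = backward if _GRAD_ENABLED else None
        return out

    # -- nonlinearities ----------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._backward = (lambda g: self._accum(g * (1.0 - y * y))) if _GRAD_ENABLED else None
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, (self,))
        out._backward = (lambda g: self._accum(g * y * (1.0 - y))) if _GRAD_ENABLED else None
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, (self,))
        out._backward = (lambda g: self._accum(g * y)) if _GRAD_ENABLED else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = (lambda g: self._accum(g / self.data)) if _GRAD_ENABLED else None
        return out

    # -- reductions / shaping ----------------------------------------
    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), (self,))

        def backward(g):
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy())

        out._backward = backward if _GRAD_ENABLED else None
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = (lambda g: self._accum(g.reshape(self.data.shape))) if _GRAD_ENABLED else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = backward if _GRAD_ENABLED else None
        return out

    def logsumexp(self, axis=None):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        val = (m + np.log(s)).squeeze() if axis is not None else (m + np.log(s)).reshape(())
        out = Tensor(val, (self,))

        def backward(g):
            soft = np.exp(self.data - m) / s
            if axis is None:
                self._accum(soft * g)
            else:
                self._accum(soft * np.expand_dims(g, axis))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    @staticmethod
    def concat(tensors: Sequence["Tensor"], axis=0) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]

        def backward(g):
            start = 0
            for t, sz in zip(tensors, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + sz)
                t._accum(g[tuple(sl)])
                start += sz

        out._backward = backward if _GRAD_ENABLED else None
        return out

    # -- backward pass ------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr=0.01, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def grad_check(fn, params: dict, eps=1e-6) -> float:
    """Max relative error between analytic and central-difference gradients.

    `fn(params) -> Tensor scalar`.  Used by the test suite to audit the tape.
    """
    loss = fn(params)
    loss.backward()
    analytic = {k: (p.grad.copy() if p.grad is not None else np.zeros_like(p.data))
                for k, p in params.items()}
    worst = 0.0
    for k, p in params.items():
        flat = p.data.ravel()
        gflat = analytic[k].ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(params).item()
            flat[i] = orig - eps
            lo = fn(params).item()
            flat[i] = orig
            num = (hi - lo) / (2 * eps)
            denom = max(1.0, abs(num), abs(gflat[i]))
            worst = max(worst, abs(num - gflat[i]) / denom)
    return worst
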