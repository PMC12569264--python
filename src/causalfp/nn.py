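"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the tensor operations the graph-attention task classifier
needs: broadcasting arithmetic, batched matmul, elementwise nonlinearities,
reductions, gather/scatter over node axes, softmax/log-softmax, and
concatenation. Gradients accumulate through a topologically sorted reverse
sweep. An Adam optimizer is included.

This is deliberately small and dense-tensor only; it is not a general
deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    # ---- arithmetic -------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def matmul(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # ---- nonlinearities ---------------------------------------------
    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)

        def backward(g, a=self, mask=mask):
            a._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g, a=self, y=y):
            a._accum(g * (1.0 - y * y))

        return self._make(y, (self,), backward)

    # ---- reductions / shape -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g, a=self, old=old):
            a._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # ---- softmax family ----------------------------------------------
    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self, s=s, axis=axis):
            inner = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - inner))

        return self._make(s, (self,), backward)

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse

        def backward(g, a=self, y=y, axis=axis):
            a._accum(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

        return self._make(y, (self,), backward)

    # ---- gather over the node axis -----------------------------------
    def gather_nodes(self, idx: np.ndarray):
        """Select rows along axis 1: input (B, N, ...) -> (B, k, ...).

        ``idx`` has shape (B, k). The backward pass scatter-adds.
        """
        B = self.data.shape[0]
        batch = np.arange(B)[:, None]
        out_data = self.data[batch, idx]

        def backward(g, a=self, idx=idx, batch=batch):
            ga = np.zeros_like(a.data)
            np.add.at(ga, (batch, idx), g)
            a._accum(ga)

        return self._make(out_data, (self,), backward)

    # ---- plumbing ----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse sweep from this (scalar) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)


def cat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)

        def backward(g, tensors=tensors, splits=splits, axis=axis):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
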