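"""Minimal vectorized reverse-mode automatic differentiation.

A deliberately small engine — just the operations the ontology-structured
encoder, the drug perceptron and the network heads need: dense affine maps,
batch normalization, tanh/ReLU/sigmoid nonlinearities, softmax attention,
concatenation, and the two training losses. Tensors wrap ``numpy.ndarray``
(always ``float64``) and record a backward closure; :func:`backward` runs the
closures in reverse topological order.

Broadcasting is supported for elementwise ops; gradients are summed back to
the original shape.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over broadcast dimensions so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS post-order; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bw():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad, other.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bw():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad * self.data, other.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                self._accum(_unbroadcast(out.grad * p * self.data ** (p - 1.0),
                                         self.shape))
            out._backward = _bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bw():
                if self.requires_grad:
                    self._accum(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ out.grad)
            out._backward = _bw
        return out

    __matmul__ = matmul

    # -- reductions & shape -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                self._accum(out.grad * (1.0 - y * y))
            out._backward = _bw
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                self._accum(out.grad * (self.data > 0.0))
            out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                self._accum(out.grad * y * (1.0 - y))
            out._backward = _bw
        return out

    def reshape(self, shape: tuple[int, ...]) -> "Tensor":
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            orig = self.data.shape

            def _bw():
                self._accum(out.grad.reshape(orig))
            out._backward = _bw
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                self._accum(out.grad * y)
            out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw():
                self._accum(out.grad / self.data)
            out._backward = _bw
        return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, routing gradients to each slice."""
    ts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis),
                 any(t.requires_grad for t in ts))
    if out.requires_grad:
        out._parents = tuple(ts)
        sizes = [t.data.shape[axis] for t in ts]
        offsets = np.cumsum([0] + sizes)

        def _bw():
            for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(out.grad[tuple(sl)])
        out._backward = _bw
    return out


def repeat_cols(w: Tensor, sizes: list[int]) -> Tensor:
    """Repeat column j of `w` sizes[j] times (gradient sums back)."""
    reps = np.asarray(sizes)
    out = Tensor(np.repeat(w.data, reps, axis=1), w.requires_grad)
    if out.requires_grad:
        out._parents = (w,)
        offsets = np.concatenate([[0], np.cumsum(reps)[:-1]])

        def _bw():
            w._accum(np.add.reduceat(out.grad, offsets, axis=1))
        out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bw():
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))
        out._backward = _bw
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 decay_mask: Iterable[float] | None = None):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay  # decoupled (AdamW-style)
        # per-parameter multiplier on weight_decay (e.g. 1.0 for dense
        # weight matrices, less for attention/norm parameters)
        self.decay_mask = (list(decay_mask) if decay_mask is not None
                           else [1.0] * len(self.params))
        if len(self.decay_mask) != len(self.params):
            raise ValueError("decay_mask length must match params")
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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            wd = self.weight_decay * self.decay_mask[i]
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + wd * p.data)
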