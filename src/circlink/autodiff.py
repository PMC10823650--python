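"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the dual graph autoencoders need: matrix
multiplication, broadcast add/sub/mul, transpose, relu, sigmoid, exp, log,
elementwise power and full sums.  Gradients are accumulated by reverse
topological sweep from a scalar loss.  Nothing here is thread-safe or
GPU-aware; graphs are rebuilt each forward pass.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the dynamically built computation graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    # ---- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, value, parents, backward) -> "Tensor":
        out = Tensor(value, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- operations ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.shape))

        return self._make(self.value - other.value, (self, other), backward)

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) - self

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.shape))

        return self._make(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        return self._make(self.value @ other.value, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        return self._make(self.value.T, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.value > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.value * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.value)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._make(e, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.value)

        return self._make(np.log(self.value), (self,), backward)

    def square(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g * 2.0 * self.value)

        return self._make(self.value**2, (self,), backward)

    def sum(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.value.sum(), (self,), backward)

    def cols(self, j0: int, j1: int) -> "Tensor":
        """Column slice [:, j0:j1] of a 2-D tensor."""

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                full[:, j0:j1] = g
                self._accum(full)

        return self._make(self.value[:, j0:j1], (self,), backward)

    def clip_min(self, lo: float) -> "Tensor":
        """Elementwise max with a constant; gradient passes where unclipped."""
        mask = self.value > lo

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.maximum(self.value, lo), (self,), backward)

    # ---- backward sweep --------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Adam:
    """Adam optimiser over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        total = np.sqrt(
            sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
        )
        if total > max_norm and total > 0:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return total

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
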