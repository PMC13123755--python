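"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the neural models in this package
(dense layers, ReLU/tanh/sigmoid, dropout masks, concatenation, embedding
lookup, log-sum-exp for mixture likelihoods). Gradients flow through a
dynamically recorded tape; ``Tensor.backward`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data**2))

        return self._make(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bwd)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(np.clip(self.data, -700, 700))

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * sig)

        return self._make(out_data, (self,), bwd)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def take_rows(self, idx: np.ndarray):
        """Row lookup (embedding-style); gradients scatter-add back."""
        idx = np.asarray(idx, dtype=np.intp)

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = bwd
    return out


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """log Σ e^x along ``axis``, numerically stable, differentiable."""
    m = x.data.max(axis=axis, keepdims=True)
    out_data = m + np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True))
    soft = np.exp(x.data - out_data)  # softmax along axis
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(g * soft)

    out = Tensor(out_data)
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)
        out._backward = bwd
    return out
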