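"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the recurrent multitask model in this package:
a :class:`Tensor` wrapping an ndarray, elementwise arithmetic with
broadcasting, matmul with batch broadcasting, the activations a GRU and
a softmax-attention layer need, reductions, concatenation and slicing.
Gradients are accumulated by a topological backward sweep from a scalar
loss.  Everything is float64 and deterministic; correctness is enforced
by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "concat", "stack", "sigmoid", "tanh", "softmax_lastaxis", "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager suppressing graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing --------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS; recursion depth would blow up on long unrolls
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g)
                other._accum(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g * other.data)
                other._accum(g * self.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g / other.data)
                other._accum(-g * self.data / (other.data**2))
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            a, b = self.data, other.data
            def backward(g):
                if a.ndim == 1 or b.ndim == 1:
                    raise NotImplementedError("matmul grads need >=2-D operands")
                self._accum(_unbroadcast(g @ b.swapaxes(-1, -2), a.shape))
                other._accum(_unbroadcast(a.swapaxes(-1, -2) @ g, b.shape))
            out._backward = backward
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a, b):
        out = self._make(self.data.swapaxes(a, b), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.swapaxes(a, b))
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)
        if out.requires_grad:
            def backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = backward
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape))
                    return
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- activations ----------------------------------------------------------
    def exp(self):
        value = np.exp(self.data)
        out = self._make(value, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * value)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out


def sigmoid(x: Tensor) -> Tensor:
    value = 1.0 / (1.0 + np.exp(-x.data))
    out = x._make(value, (x,), None)
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * value * (1 - value))
    return out


def tanh(x: Tensor) -> Tensor:
    value = np.tanh(x.data)
    out = x._make(value, (x,), None)
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * (1 - value**2))
    return out


def softmax_lastaxis(x: Tensor) -> Tensor:
    """Numerically stable softmax along the last axis."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    value = e / e.sum(axis=-1, keepdims=True)
    out = x._make(value, (x,), None)
    if out.requires_grad:
        def backward(g):
            dot = (g * value).sum(axis=-1, keepdims=True)
            x._accum(value * (g - dot))
        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        def backward(g):
            offset = 0
            for t, size in zip(tensors, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(offset, offset + size)
                t._accum(g[tuple(sl)])
                offset += size
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        def backward(g):
            pieces = np.moveaxis(g, axis, 0)
            for t, piece in zip(tensors, pieces):
                t._accum(piece)
        out._backward = backward
    return out
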