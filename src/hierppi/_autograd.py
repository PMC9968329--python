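"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations needed by the graph encoders live here: broadcasting
arithmetic, matrix products, ReLU/tanh, reductions, row gathering,
concatenation, and a numerically stable binary-cross-entropy-with-logits
primitive.  Everything is float64.  Gradient correctness is verified against
central finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph building (evaluation mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        out_data = _sigmoid(self.data)
        return Tensor._make(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_rows(self, idx):
        """Gather rows; gradient scatters back (duplicate indices accumulate)."""
        idx = np.asarray(idx, dtype=np.intp)
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return Tensor._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the graph
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate into .grad
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = grads[key] + pg if key in grads else pg


def concat_rows(tensors) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=0)
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(g[offsets[i]: offsets[i + 1]] for i in range(len(tensors)))

    return Tensor._make(out_data, tuple(tensors), backward)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two 2-D tensors along axis 1 (pair embedding)."""
    out_data = np.concatenate([a.data, b.data], axis=1)
    na = a.data.shape[1]

    def backward(g):
        return (g[:, :na], g[:, na:])

    return Tensor._make(out_data, (a, b), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy from logits.

    Stable form: max(x,0) - x*y + log(1+exp(-|x|)); gradient is sigmoid(x)-y.
    """
    x = logits.data
    y = np.asarray(targets, dtype=np.float64)
    out_data = np.maximum(x, 0.0) - x * y + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        return (g * (_sigmoid(x) - y),)

    return Tensor._make(out_data, (logits,), backward)
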