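"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small pathway-masked networks on CPU, and the
interpretation chain needs exact gradients with respect to *inputs*
(for integrated-gradient attributions) as well as parameters.  A tiny
tape-based engine over ``float64`` numpy arrays covers both needs with
tolerances tight enough for the numerical identity checks in the test
suite; a full deep-learning framework is deliberately not a dependency.

Only the operations the fusion network uses are implemented: broadcasted
arithmetic, (batched) matmul, the LeakyReLU / GELU / sigmoid / softplus
nonlinearities, softmax, reductions, reshaping, concatenation and basic
slicing.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concatenate"]

_SQRT_2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcasted axes."""
    if grad.shape == shape:
        return grad
    # sum away extra leading dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape),
            )

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(
            np.matmul(self.data, other.data),
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim > 1 else g * b
            else:
                ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim > 1 else np.multiply.outer(g, b)
            gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 else np.multiply.outer(a, g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # --------------------------------------------------------- nonlinearities
    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        out = Tensor(
            np.where(self.data > 0, self.data, slope * self.data),
            self.requires_grad,
            (self,),
        )
        out._backward = lambda g: (g * np.where(self.data > 0, 1.0, slope),)
        return out

    def gelu(self) -> "Tensor":
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT_2))
        out = Tensor(x * cdf, self.requires_grad, (self,))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        out._backward = lambda g: (g * (cdf + x * pdf),)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def softplus(self) -> "Tensor":
        # numerically stable log(1 + exp(x))
        out = Tensor(np.logaddexp(0.0, self.data), self.requires_grad, (self,))
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out._backward = lambda g: (g * s,)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        out._backward = lambda g: (g * e,)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def backward(g):
            inner = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - inner),)

        out._backward = backward
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        out._backward = backward
        return out

    # --------------------------------------------------------------- backward
    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every graph node's ``.grad``."""
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if parent.grad is None:
                    parent.grad = np.array(pgrad, dtype=np.float64)
                else:
                    parent.grad = parent.grad + pgrad

    def zero_grad(self) -> None:
        self.grad = None


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            grads.append(g[tuple(idx)])
        return tuple(grads)

    out._backward = backward
    return out
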