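"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the masked graph autoencoder: a ``Tensor``
wrapping an ``ndarray`` with a gradient slot, the dozen array operations the
encoder and decoders compose (matmul, broadcast add/mul, relu, sigmoid, log,
reductions, row gather, concatenation), topological-order backpropagation,
and an Adam optimizer.  Gradients are checked against central finite
differences in the test suite.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were 1 in the original shape
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("value", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_value = self.value + other.value

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.shape))

        return self._make(out_value, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(grad):
            if self.requires_grad:
                self._accumulate(-grad)

        return self._make(-self.value, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_value = self.value * other.value

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.value, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.value, other.shape))

        return self._make(out_value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out_value = self.value / other.value

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad / other.value, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-grad * self.value / other.value**2, other.shape)
                )

        return self._make(out_value, (self, other), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_value = self.value @ other.value

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad @ other.value.T)
            if other.requires_grad:
                other._accumulate(self.value.T @ grad)

        return self._make(out_value, (self, other), backward)

    def square(self) -> "Tensor":
        return self * self

    # -- nonlinearities ---------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.value > 0

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * mask)

        return self._make(self.value * mask, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.2) -> "Tensor":
        slope = np.where(self.value > 0, 1.0, negative_slope)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * slope)

        return self._make(self.value * slope, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_value = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out_value * (1.0 - out_value))

        return self._make(out_value, (self,), backward)

    def exp(self) -> "Tensor":
        out_value = np.exp(self.value)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out_value)

        return self._make(out_value, (self,), backward)

    def log(self) -> "Tensor":
        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad / self.value)

        return self._make(np.log(self.value), (self,), backward)

    def clip(self, low: float, high: float) -> "Tensor":
        """Clamp values; gradient passes only through unclipped entries."""
        inside = (self.value >= low) & (self.value <= high)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * inside)

        return self._make(np.clip(self.value, low, high), (self,), backward)

    # -- reductions and reshaping -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_value = self.value.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(out_value, (self,), backward)

    def mean(self, axis=None) -> "Tensor":
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    @property
    def T(self) -> "Tensor":
        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.T)

        return self._make(self.value.T, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(self.shape))

        return self._make(self.value.reshape(*shape), (self,), backward)

    def gather_rows(self, index) -> "Tensor":
        """Select rows by integer index; gradient scatter-adds back."""
        index = np.asarray(index, dtype=np.intp)

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, index, grad)
                self._accumulate(full)

        return self._make(self.value[index], (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        sizes = [t.value.shape[axis] for t in tensors]
        out_value = np.concatenate([t.value for t in tensors], axis=axis)

        def backward(grad):
            offset = 0
            for t, size in zip(tensors, sizes):
                if t.requires_grad:
                    sl = [slice(None)] * grad.ndim
                    sl[axis] = slice(offset, offset + size)
                    t._accumulate(grad[tuple(sl)])
                offset += size

        out = Tensor(out_value)
        if any(t.requires_grad for t in tensors):
            out.requires_grad = True
            out._parents = tuple(tensors)
            out._backward = backward
        return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform weight initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        parameters: list[Tensor],
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.parameters = list(parameters)
        self.learning_rate = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in self.parameters]
        self._v = [np.zeros_like(p.value) for p in self.parameters]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        for i, p in enumerate(self.parameters):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g**2
            m_hat = self._m[i] / (1 - self.beta1**self._t)
            v_hat = self._v[i] / (1 - self.beta2**self._t)
            p.value -= self.learning_rate * m_hat / (np.sqrt(v_hat) + self.eps)
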