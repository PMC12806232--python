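"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps a float64
``ndarray``, records the operations applied to it, and ``backward()`` walks
the tape in reverse topological order accumulating gradients.  Only the
operations the model needs are implemented (affine maps, element-wise
nonlinearities, softmax, concatenation, row gathering, reductions), all with
NumPy broadcasting; gradients of broadcast operands are summed back to the
operand's shape.  Everything runs in float64 so numerical oracles can be
checked to tight tolerances.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "as_tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many epochs of layers)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data)
        out._prev = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data)
        out._prev = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data)
        out._prev = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data)
        out._prev = (self, other)
        a, b = self.data, other.data

        def bw(g):
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul gradient needs 2-D operands")
            self._accumulate(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            other._accumulate(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        out._prev = (self,)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.data.T)
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g.T)
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._prev = (self,)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------- nonlinearities
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0))
        out._prev = (self,)
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        out._backward = bw
        return out

    def sigmoid(self):
        s = expit(self.data)
        out = Tensor(s)
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t)
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e)
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data))
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r)
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g * 0.5 / r)
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p)
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s)
        out._prev = (self,)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        out._backward = bw
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls)
        out._prev = (self,)
        s = np.exp(ls)

        def bw(g):
            self._accumulate(g - s * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._prev = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors (Kingma & Ba defaults)."""

    def __init__(self, params, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
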