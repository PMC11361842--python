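"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the connectivity encoder stack: dense linear maps,
ReLU, row softmax, layer normalization, dropout masks, batched matmul for
multihead attention, row gathering for loss restriction, and an Adam
optimizer.  Float64 throughout; gradients are accumulated over a
topologically sorted tape.  Correctness is established by central
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum out broadcast axes so grad matches the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data - other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(-g, other.data.shape))

        out._backward = backward
        return out

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    def square(self):
        out = Tensor(self.data ** 2, parents=(self,))
        out._backward = lambda g: (2.0 * self.data * g,)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def mean(self):
        out = Tensor(self.data.mean(), parents=(self,))
        n = self.data.size
        out._backward = lambda g: (np.full_like(self.data, float(g) / n),)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = lambda g: (g.transpose(*inverse),)
        return out

    def softmax_last(self):
        """Softmax over the last axis (rows of an attention score matrix)."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, parents=(self,))

        def backward(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            return ((g - dot) * s,)

        out._backward = backward
        return out

    def layer_norm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean / unit variance (no affine)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out = Tensor(xhat, parents=(self,))

        def backward(g):
            gm = g.mean(axis=-1, keepdims=True)
            gx = (g * xhat).mean(axis=-1, keepdims=True)
            return (inv * (g - gm - xhat * gx),)

        out._backward = backward
        return out

    def gather_rows(self, index: np.ndarray):
        """Select rows by integer index (loss restriction to a gene subset)."""
        index = np.asarray(index, dtype=int)
        out = Tensor(self.data[index], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            return (full,)

        out._backward = backward
        return out

    # -- backward pass ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64, copy=True)
                else:
                    parent.grad += g


def concat_last(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the last axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1),
                 parents=tuple(tensors))
    widths = [t.data.shape[-1] for t in tensors]
    splits = np.cumsum(widths)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=-1))

    out._backward = backward
    return out


def parameter(rng: np.random.Generator, fan_in: int, fan_out: int,
              shape=None) -> Tensor:
    """Glorot-uniform initialized trainable tensor."""
    if shape is None:
        shape = (fan_in, fan_out)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros_parameter(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Adam:
    """Adam optimizer over a list of trainable tensors."""

    def __init__(self, params: list[Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
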