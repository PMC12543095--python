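"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The training objective combines reconstruction, contrastive and KL terms whose
gradients flow through encoders, cluster centers, attention projections and the
clustering head simultaneously; a small tape-based engine keeps those gradients
exact without hand-deriving each composite backward pass.

Every public function dispatches on input type: given plain ``ndarray`` inputs
it computes with NumPy directly (used for full-dataset inference forwards),
given :class:`Tensor` inputs it records the operation for backpropagation.
Model code is therefore written once and serves both paths.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "value",
    "exp",
    "log",
    "sqrt",
    "relu",
    "clip",
    "tsum",
    "tmean",
    "matmul",
    "transpose",
    "concat",
    "cols",
    "softmax",
    "layer_norm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` dispatch to the Tensor's reflected operator
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for p, pg in zip(node._parents, node._backward(g)):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        a, b = self, _wrap(other)
        return Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, _wrap(other)
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _wrap(other)
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, c):
        if not np.isscalar(c):
            raise TypeError("only scalar exponents are supported")
        a = self
        return Tensor._make(
            a.data**c, (a,), lambda g: (g * c * a.data ** (c - 1),)
        )

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return transpose(self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng=None, scale=None) -> Tensor:
    """Create a trainable leaf tensor."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def value(x):
    """Underlying ndarray of ``x`` whether it is a Tensor or an array."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


# -- dispatched functions ---------------------------------------------------

def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    out_data = np.exp(x.data)
    return Tensor._make(out_data, (x,), lambda g: (g * out_data,))


def log(x):
    if not isinstance(x, Tensor):
        return np.log(x)
    return Tensor._make(np.log(x.data), (x,), lambda g: (g / x.data,))


def sqrt(x):
    if not isinstance(x, Tensor):
        return np.sqrt(x)
    out_data = np.sqrt(x.data)
    return Tensor._make(out_data, (x,), lambda g: (g / (2.0 * out_data),))


def relu(x):
    if not isinstance(x, Tensor):
        return np.maximum(x, 0.0)
    return Tensor._make(
        np.maximum(x.data, 0.0), (x,), lambda g: (g * (x.data > 0),)
    )


def clip(x, lo, hi):
    """Clamp with straight-through gradient inside [lo, hi]."""
    if not isinstance(x, Tensor):
        return np.clip(x, lo, hi)
    mask = (x.data >= lo) & (x.data <= hi)
    return Tensor._make(np.clip(x.data, lo, hi), (x,), lambda g: (g * mask,))


def tsum(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis, keepdims=keepdims)
    shape = x.shape

    def back(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, shape).copy(),)

    return Tensor._make(np.sum(x.data, axis=axis, keepdims=keepdims), (x,), back)


def tmean(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.mean(x, axis=axis, keepdims=keepdims)
    n = x.data.size if axis is None else x.data.shape[axis]
    return tsum(x, axis=axis, keepdims=keepdims) * (1.0 / n)


def matmul(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.asarray(a) @ np.asarray(b)
    a, b = _wrap(a), _wrap(b)
    return Tensor._make(
        a.data @ b.data,
        (a, b),
        lambda g: (g @ b.data.T, a.data.T @ g),
    )


def transpose(x):
    if not isinstance(x, Tensor):
        return np.asarray(x).T
    return Tensor._make(x.data.T, (x,), lambda g: (g.T,))


def concat(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    parts = [_wrap(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([p.data for p in parts], axis=axis), tuple(parts), back
    )


def cols(x, start, stop):
    """Column slice x[:, start:stop]."""
    if not isinstance(x, Tensor):
        return np.asarray(x)[:, start:stop]

    def back(g):
        full = np.zeros_like(x.data)
        full[:, start:stop] = g
        return (full,)

    return Tensor._make(x.data[:, start:stop], (x,), back)


def softmax(x, axis=-1):
    """Numerically stable softmax along ``axis``."""
    shift = np.max(value(x), axis=axis, keepdims=True)
    e = exp(x - shift)
    return e / tsum(e, axis=axis, keepdims=True)


def layer_norm(x, eps: float = 1e-5):
    """Per-row (feature-axis) layer normalization without affine parameters."""
    mu = tmean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = tmean(xc * xc, axis=-1, keepdims=True)
    return xc / sqrt(var + eps)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
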