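"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the attention network needs: broadcast
arithmetic, matmul, slicing, reshape, concatenation, axis reductions and the
usual nonlinearities.  Every functional primitive (`matmul`, `relu`, ...)
dispatches on its arguments: called with plain numpy arrays it computes in
numpy and returns an array, called with at least one :class:`Tensor` it
records the operation on the tape.  This lets the forward pass be written
once and reused for both inference and training.

Gradients are accumulated by a topological-order sweep from the scalar loss.
Correctness is asserted against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "div",
    "matmul",
    "relu",
    "leaky_relu",
    "sigmoid",
    "exp",
    "softplus",
    "concat",
    "reduce_sum",
    "take",
    "reshape",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    #: make numpy defer binary ops to the reflected Tensor implementations
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ----------------------------------------------------
    def backward(self, seed=None):
        """Accumulate gradients of `self` (a scalar unless `seed` given)."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar tensor")
            seed = np.ones_like(self.data)
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
        self.grad = np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis=axis, keepdims=keepdims)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _is_tensor(*args) -> bool:
    return any(isinstance(a, Tensor) for a in args)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- binary ops --------------------------------------------------------------

def add(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) + np.asarray(b)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    out._backward = backward
    return out


def mul(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) * np.asarray(b)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(g * b.data)
        if b.requires_grad:
            b._accum(g * a.data)

    out._backward = backward
    return out


def div(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) / np.asarray(b)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(g / b.data)
        if b.requires_grad:
            b._accum(-g * a.data / (b.data * b.data))

    out._backward = backward
    return out


def matmul(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) @ np.asarray(b)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, parents=(a, b))
    a_d, b_d = a.data, b.data

    def backward(g):
        g = np.asarray(g)
        if a.requires_grad:
            if a_d.ndim == 2 and b_d.ndim == 2:
                a._accum(g @ b_d.T)
            elif a_d.ndim == 2 and b_d.ndim == 1:
                a._accum(np.outer(g, b_d))
            elif a_d.ndim == 1 and b_d.ndim == 2:
                a._accum(b_d @ g)
            else:  # 1-D @ 1-D
                a._accum(g * b_d)
        if b.requires_grad:
            if a_d.ndim == 2 and b_d.ndim == 2:
                b._accum(a_d.T @ g)
            elif a_d.ndim == 2 and b_d.ndim == 1:
                b._accum(a_d.T @ g)
            elif a_d.ndim == 1 and b_d.ndim == 2:
                b._accum(np.outer(a_d, g))
            else:
                b._accum(g * a_d)

    out._backward = backward
    return out


def transpose(a):
    if not _is_tensor(a):
        return np.asarray(a).T
    out = Tensor(a.data.T, parents=(a,))

    def backward(g):
        a._accum(np.asarray(g).T)

    out._backward = backward
    return out


# -- unary nonlinearities -----------------------------------------------------

def relu(x):
    if not _is_tensor(x):
        return np.maximum(np.asarray(x), 0.0)
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    out._backward = backward
    return out


def leaky_relu(x, slope: float = 0.2):
    if not _is_tensor(x):
        x = np.asarray(x, dtype=np.float64)
        return np.where(x > 0, x, slope * x)
    grad_factor = np.where(x.data > 0, 1.0, slope)
    out = Tensor(np.where(x.data > 0, x.data, slope * x.data), parents=(x,))

    def backward(g):
        x._accum(g * grad_factor)

    out._backward = backward
    return out


def sigmoid(x):
    if not _is_tensor(x):
        from scipy.special import expit

        return expit(np.asarray(x, dtype=np.float64))
    from scipy.special import expit

    s = expit(x.data)
    out = Tensor(s, parents=(x,))

    def backward(g):
        x._accum(g * s * (1.0 - s))

    out._backward = backward
    return out


def exp(x):
    if not _is_tensor(x):
        return np.exp(np.asarray(x, dtype=np.float64))
    e = np.exp(x.data)
    out = Tensor(e, parents=(x,))

    def backward(g):
        x._accum(g * e)

    out._backward = backward
    return out


def softplus(x):
    """log(1 + exp(x)), numerically stable."""
    if not _is_tensor(x):
        return np.logaddexp(0.0, np.asarray(x, dtype=np.float64))
    from scipy.special import expit

    out = Tensor(np.logaddexp(0.0, x.data), parents=(x,))
    s = expit(x.data)

    def backward(g):
        x._accum(g * s)

    out._backward = backward
    return out


# -- structural ops -----------------------------------------------------------

def concat(parts, axis: int = -1):
    if not _is_tensor(*parts):
        return np.concatenate([np.asarray(p) for p in parts], axis=axis)
    parts = [_wrap(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for p, piece in zip(parts, np.split(np.asarray(g), splits, axis=axis)):
            if p.requires_grad:
                p._accum(piece)

    out._backward = backward
    return out


def reduce_sum(x, axis=None, keepdims: bool = False):
    if not _is_tensor(x):
        return np.asarray(x).sum(axis=axis, keepdims=keepdims)
    out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,))
    shape = x.data.shape

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(np.broadcast_to(g, shape))

    out._backward = backward
    return out


def take(x, idx):
    """Basic/advanced indexing with scatter-add backward."""
    if not _is_tensor(x):
        return np.asarray(x)[idx]
    out = Tensor(x.data[idx], parents=(x,))
    shape = x.data.shape

    def backward(g):
        full = np.zeros(shape, dtype=np.float64)
        np.add.at(full, idx, np.asarray(g))
        x._accum(full)

    out._backward = backward
    return out


def reshape(x, shape):
    if not _is_tensor(x):
        return np.asarray(x).reshape(shape)
    old = x.data.shape
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def backward(g):
        x._accum(np.asarray(g).reshape(old))

    out._backward = backward
    return out
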