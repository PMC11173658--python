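"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package (feature transform, multi-head graph attention,
semantic attention, contrastive and prediction losses) is small enough that a
compact tape-based autodiff core over dense float64 arrays is both sufficient
and fully deterministic on one CPU.  Only the primitives the model needs are
implemented; gradients are checked against finite differences in the test
suite.

Conventions
-----------
* ``Tensor`` wraps a ``numpy.ndarray``; ``requires_grad`` propagates through
  every op.
* ``Tensor.backward()`` may only be called on a scalar and accumulates
  ``.grad`` (a numpy array) on every reachable tensor with
  ``requires_grad=True``.
* Broadcasting follows numpy; gradients are un-broadcast (summed) back to the
  parent's shape.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "parameter",
    "concat",
    "stack",
    "exp",
    "log",
    "tanh",
    "relu",
    "elu",
    "leaky_relu",
    "prelu",
    "softmax",
    "masked_softmax",
    "log_softmax",
    "xavier_uniform",
    "Adam",
    "grad_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _grad_fn: Callable | None = None,
        name: str | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._grad_fn = _grad_fn
        self.grad = None
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep for long loss chains)
        visit_stack: list[tuple[Tensor, bool]] = [(self, False)]
        while visit_stack:
            node, processed = visit_stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visit_stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    visit_stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._grad_fn is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._grad_fn is None:
                continue
            parent_grads = node._grad_fn(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                pg = _unbroadcast(np.asarray(pg), p.data.shape)
                if p._grad_fn is None:
                    p.grad = pg if p.grad is None else p.grad + pg
                else:
                    key = id(p)
                    grads[key] = pg if key not in grads else grads[key] + pg
        del stack

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            _parents=(self, other),
            _grad_fn=lambda g: (g, g),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _grad_fn=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _grad_fn=lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(self, other),
            _grad_fn=lambda g: (g / other.data, -g * self.data / other.data**2),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        return Tensor(
            self.data**p,
            _parents=(self,),
            _grad_fn=lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data @ other.data,
            _parents=(self, other),
            _grad_fn=lambda g: (g @ other.data.T, self.data.T @ g),
        )

    @property
    def T(self):
        return Tensor(self.data.T, _parents=(self,), _grad_fn=lambda g: (g.T,))

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def grad_fn(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            _parents=(self,),
            _grad_fn=grad_fn,
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape / idx
    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            _parents=(self,),
            _grad_fn=lambda g: (g.reshape(old),),
        )

    def take_rows(self, idx):
        """Gather rows (axis 0) by integer index array; rows may repeat."""
        idx = np.asarray(idx, dtype=np.intp)

        def grad_fn(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.data[idx], _parents=(self,), _grad_fn=grad_fn)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=(self,),
            _grad_fn=lambda g: (g.transpose(inv),),
        )

    def diag(self):
        """Diagonal of a square matrix as a vector."""

        def grad_fn(g):
            out = np.zeros_like(self.data)
            np.fill_diagonal(out, g)
            return (out,)

        return Tensor(np.diag(self.data), _parents=(self,), _grad_fn=grad_fn)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, name: str | None = None) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True, name=name)


# ------------------------------------------------------------------ functions
def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _grad_fn=grad_fn,
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def grad_fn(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _grad_fn=grad_fn,
    )


def bmm(x: Tensor, y: Tensor) -> Tensor:
    """Batched matrix product of two stacks with identical leading shape."""
    x, y = as_tensor(x), as_tensor(y)
    if x.data.shape[:-2] != y.data.shape[:-2]:
        raise ValueError("bmm requires identical batch shapes")

    def grad_fn(g):
        return (g @ np.swapaxes(y.data, -1, -2), np.swapaxes(x.data, -1, -2) @ g)

    return Tensor(x.data @ y.data, _parents=(x, y), _grad_fn=grad_fn)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return Tensor(out, _parents=(x,), _grad_fn=lambda g: (g * out,))


def log(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Natural log with the argument clipped below at ``eps``."""
    x = as_tensor(x)
    clipped = np.maximum(x.data, eps)
    return Tensor(
        np.log(clipped),
        _parents=(x,),
        _grad_fn=lambda g: (g / clipped * (x.data >= eps),),
    )


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)
    return Tensor(out, _parents=(x,), _grad_fn=lambda g: (g * (1 - out**2),))


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(
        np.maximum(x.data, 0.0),
        _parents=(x,),
        _grad_fn=lambda g: (g * (x.data > 0),),
    )


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = as_tensor(x)
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out = np.where(x.data > 0, x.data, neg)
    return Tensor(
        out,
        _parents=(x,),
        _grad_fn=lambda g: (g * np.where(x.data > 0, 1.0, neg + alpha),),
    )


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    return Tensor(
        np.where(x.data > 0, x.data, slope * x.data),
        _parents=(x,),
        _grad_fn=lambda g: (g * np.where(x.data > 0, 1.0, slope),),
    )


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a learnable scalar slope."""
    x, slope = as_tensor(x), as_tensor(slope)
    pos = x.data > 0

    def grad_fn(g):
        gx = g * np.where(pos, 1.0, slope.data)
        gs = np.sum(g * np.where(pos, 0.0, x.data))
        return (gx, np.full(slope.data.shape, gs))

    return Tensor(
        np.where(pos, x.data, slope.data * x.data),
        _parents=(x, slope),
        _grad_fn=grad_fn,
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(shift)
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax restricted to ``mask`` support; rows must have >=1 unmasked entry.

    The max-shift uses detached data, which leaves both the value and the
    gradient of the softmax unchanged.
    """
    x = as_tensor(x)
    mask = np.asarray(mask, dtype=float)
    neg = np.where(mask > 0, x.data, -np.inf)
    shift = neg.max(axis=axis, keepdims=True)
    e = exp(x - Tensor(shift)) * Tensor(mask)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - log(exp(z).sum(axis=axis, keepdims=True))


# ---------------------------------------------------------------------- init
def xavier_uniform(rng: np.random.Generator, shape: tuple, name: str | None = None) -> Tensor:
    """Glorot/Xavier uniform initialization (documented default init)."""
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0] if len(shape) > 1 else shape[0]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=shape), name=name)


# ----------------------------------------------------------------- optimizer
class Adam:
    """Standard Adam over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# -------------------------------------------------------------- verification
def grad_check(fn: Callable[[], Tensor], params: Sequence[Tensor],
               eps: float = 1e-6, rtol: float = 1e-4, atol: float = 1e-6) -> bool:
    """Compare analytic gradients of scalar ``fn()`` with central differences."""
    for p in params:
        p.grad = None
    loss = fn()
    loss.backward()
    ok = True
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
        num = np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        nflat = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = fn().item()
            flat[i] = orig - eps
            lm = fn().item()
            flat[i] = orig
            nflat[i] = (lp - lm) / (2 * eps)
        if not np.allclose(analytic, num, rtol=rtol, atol=atol):
            ok = False
    return ok
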