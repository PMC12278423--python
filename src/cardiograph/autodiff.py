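"""Reverse-mode automatic differentiation over numpy float64 arrays.

This is the numerics core of the package: every differentiable quantity
(attention weights, GRU recurrences, loss terms) is built from the small
set of vectorized primitives below, so a single backward pass yields exact
gradients for training and for finite-difference verification. The engine
is deliberately minimal — dense float64 only, no views sharing storage,
no in-place mutation of tensors that already participate in a graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "div", "neg", "matmul",
    "exp", "log", "tanh", "sigmoid", "relu", "sqrt", "absolute", "power",
    "tsum", "tmean", "concat", "getitem", "segment_sum", "reshape",
    "transpose", "stack", "backward", "Adam", "parameters",
]


class Tensor:
    """A dense float64 array plus the tape links needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _accum(t: Tensor, g: np.ndarray) -> None:
    g = _unbroadcast(np.asarray(g, dtype=np.float64), t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


# -- primitives ---------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        _accum(a, g)
        _accum(b, g)

    return _make(a.data + b.data, (a, b), bwd)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        _accum(a, g)
        _accum(b, -g)

    return _make(a.data - b.data, (a, b), bwd)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _make(a.data * b.data, (a, b), bwd)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data ** 2))

    return _make(a.data / b.data, (a, b), bwd)


def neg(a):
    a = as_tensor(a)

    def bwd(g):
        _accum(a, -g)

    return _make(-a.data, (a,), bwd)


def power(a, p: float):
    a = as_tensor(a)
    p = float(p)

    def bwd(g):
        _accum(a, g * p * np.power(a.data, p - 1.0))

    return _make(np.power(a.data, p), (a,), bwd)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    na, nb = a.data.ndim, b.data.ndim
    if na > 2 or nb > 2:
        raise ValueError("matmul supports 1-D and 2-D operands only")

    def bwd(g):
        if na == 2 and nb == 2:          # (m,k)@(k,n)
            _accum(a, g @ b.data.T)
            _accum(b, a.data.T @ g)
        elif na == 1 and nb == 2:        # (k,)@(k,n) -> (n,)
            _accum(a, b.data @ g)
            _accum(b, np.outer(a.data, g))
        elif na == 2 and nb == 1:        # (m,k)@(k,) -> (m,)
            _accum(a, np.outer(g, b.data))
            _accum(b, a.data.T @ g)
        else:                            # (k,)@(k,) -> scalar
            _accum(a, g * b.data)
            _accum(b, g * a.data)

    return _make(a.data @ b.data, (a, b), bwd)


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), bwd)


def log(a):
    a = as_tensor(a)

    def bwd(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), bwd)


def tanh(a):
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def bwd(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), bwd)


def sigmoid(a):
    a = as_tensor(a)
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def bwd(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bwd)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def bwd(g):
        _accum(a, g * mask)

    return _make(np.where(mask, a.data, 0.0), (a,), bwd)


def sqrt(a):
    a = as_tensor(a)
    out_data = np.sqrt(a.data)

    def bwd(g):
        _accum(a, g * 0.5 / out_data)

    return _make(out_data, (a,), bwd)


def absolute(a):
    a = as_tensor(a)
    sign = np.sign(a.data)

    def bwd(g):
        _accum(a, g * sign)

    return _make(np.abs(a.data), (a,), bwd)


def tsum(a, axis=None, keepdims: bool = False):
    a = as_tensor(a)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)


def tmean(a, axis=None, keepdims: bool = False):
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(parts, axis: int = 0):
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(p, g[tuple(sl)])

    return _make(np.concatenate([p.data for p in parts], axis=axis), parts, bwd)


def stack(parts, axis: int = 0):
    parts = [as_tensor(p) for p in parts]

    def bwd(g):
        for i, p in enumerate(parts):
            _accum(p, np.take(g, i, axis=axis))

    return _make(np.stack([p.data for p in parts], axis=axis), parts, bwd)


def getitem(a, idx):
    a = as_tensor(a)

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        _accum(a, ga)

    return _make(a.data[idx], (a,), bwd)


def segment_sum(a, segment_ids: np.ndarray, num_segments: int):
    """Sum rows of `a` into `num_segments` buckets given by `segment_ids`."""
    a = as_tensor(a)
    ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, ids, a.data)

    def bwd(g):
        _accum(a, g[ids])

    return _make(out_data, (a,), bwd)


def reshape(a, shape):
    a = as_tensor(a)

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), bwd)


def transpose(a, axes=None):
    a = as_tensor(a)
    fwd_axes = axes if axes is not None else tuple(range(a.data.ndim))[::-1]
    inv = np.argsort(fwd_axes)

    def bwd(g):
        _accum(a, g.transpose(inv))

    return _make(a.data.transpose(fwd_axes), (a,), bwd)


# -- graph traversal ----------------------------------------------------

def backward(t: Tensor, grad=None) -> None:
    """Accumulate d(t)/d(leaf) into .grad of every reachable tensor."""
    if not t.requires_grad:
        raise ValueError("backward() on a tensor that does not require grad")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack_ = [(t, False)]
    while stack_:
        node, done = stack_.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack_.append((p, False))
    t.grad = np.ones_like(t.data) if grad is None else np.asarray(grad, dtype=np.float64)
    for node in reversed(topo):
        if node._backward is not None:
            node._backward(node.grad)


def parameters(obj) -> list[Tensor]:
    """Collect grad-requiring tensors from (nested) containers/dataclasses."""
    found: list[Tensor] = []
    seen: set[int] = set()

    def walk(x):
        if isinstance(x, Tensor):
            if x.requires_grad and id(x) not in seen:
                seen.add(id(x))
                found.append(x)
        elif isinstance(x, dict):
            for v in x.values():
                walk(v)
        elif isinstance(x, (list, tuple)):
            for v in x:
                walk(v)
        elif hasattr(x, "__dataclass_fields__"):
            for f in x.__dataclass_fields__:
                walk(getattr(x, f))

    walk(obj)
    return found


class Adam:
    """Adam optimizer over a flat list of leaf tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
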