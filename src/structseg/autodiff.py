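"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's trainable modules (dictionary adapters, prompt branch, gating
head, frequency diffusion, the miniature segmenter) are all expressed in
terms of the primitives defined here.  The design is a classic dynamic tape:
each operation returns a :class:`Tensor` that remembers its parents and a
closure that routes the upstream gradient to them; :meth:`Tensor.backward`
walks the tape in reverse topological order.

Every public primitive is *dispatching*: called on plain numpy arrays it
performs the forward computation only, called on Tensors it records the
graph.  This lets the mathematical operations of the library be written once
and reused both as plain array functions (with closed-form oracles in the
tests) and inside the differentiable model.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.fft import dctn, idctn
from scipy.special import erf

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "add", "mul", "matmul", "exp", "log", "sqrt", "tanh", "sigmoid",
    "softplus", "relu", "gelu", "identity", "maximum",
    "tsum", "tmean", "tmax", "reshape", "transpose", "concatenate",
    "softmax", "dct_filter", "ACTIVATIONS",
    "Module", "Linear", "LayerNorm", "AdamW",
]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Tensor:
    """An N-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "group")
    __array_ufunc__ = None  # force numpy to defer to our reflected operators

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None
        self.group = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative DFS post-order gives a reverse topological schedule
        topo, seen = [], {id(self)}
        stack = [(self, iter(self._parents))]
        while stack:
            cur, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(cur)
                stack.pop()
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return _div(self, other)

    def __rtruediv__(self, other):
        return _div(other, self)

    def __pow__(self, n):
        return _pow(self, n)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __getitem__(self, idx):
        return _getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A Tensor that is updated by optimisers (``requires_grad=True``)."""

    def __init__(self, data, group: str | None = None):
        super().__init__(data, requires_grad=True)
        self.group = group


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _node(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = _unbroadcast(np.asarray(g, dtype=t.data.dtype), t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


# ---------------------------------------------------------------------------
# elementwise primitives
# ---------------------------------------------------------------------------

def _coerce_pair(a, b):
    """Wrap operands as Tensors; scalar constants adopt the tensor's dtype
    so float32 graphs are not silently upcast."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor) and np.ndim(b) == 0:
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(b, Tensor) and not isinstance(a, Tensor) and np.ndim(a) == 0:
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return as_tensor(a), as_tensor(b)


def add(a, b):
    if not _is_t(a, b):
        return np.asarray(a) + np.asarray(b)
    a, b = _coerce_pair(a, b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _node(out_data, (a, b), backward)


def mul(a, b):
    if not _is_t(a, b):
        return np.asarray(a) * np.asarray(b)
    a, b = _coerce_pair(a, b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _node(out_data, (a, b), backward)


def _div(a, b):
    if not _is_t(a, b):
        return np.asarray(a) / np.asarray(b)
    a, b = _coerce_pair(a, b)
    out_data = a.data / b.data

    def backward(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data * b.data))

    return _node(out_data, (a, b), backward)


def _pow(a, n: float):
    if not _is_t(a):
        return np.asarray(a) ** n
    a = as_tensor(a)
    out_data = a.data ** n

    def backward(g):
        _accum(a, g * n * a.data ** (n - 1))

    return _node(out_data, (a,), backward)


def _unary(a, fwd, grad_fn):
    if not _is_t(a):
        a = np.asarray(a)
        return fwd(a if a.dtype in (np.float32, np.float64) else a.astype(np.float64))
    a = as_tensor(a)
    out_data = fwd(a.data)

    def backward(g):
        _accum(a, g * grad_fn(a.data, out_data))

    return _node(out_data, (a,), backward)


def exp(a):
    return _unary(a, np.exp, lambda x, y: y)


def log(a):
    return _unary(a, np.log, lambda x, y: 1.0 / x)


def sqrt(a):
    return _unary(a, np.sqrt, lambda x, y: 0.5 / y)


def tanh(a):
    return _unary(a, np.tanh, lambda x, y: 1.0 - y * y)


def sigmoid(a):
    def fwd(x):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    return _unary(a, fwd, lambda x, y: y * (1.0 - y))


def softplus(a):
    def fwd(x):
        return np.logaddexp(0.0, x)

    def grad(x, y):
        return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, 0, None))),
                        np.exp(np.clip(x, None, 0)) / (1.0 + np.exp(np.clip(x, None, 0))))

    return _unary(a, fwd, grad)


def relu(a):
    return _unary(a, lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(np.float64))


def gelu(a):
    """Exact (erf-based) Gaussian error linear unit."""

    def fwd(x):
        return 0.5 * x * (1.0 + erf(x / _SQRT2))

    def grad(x, y):
        return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)

    return _unary(a, fwd, grad)


def identity(a):
    return a


ACTIVATIONS = {
    "gelu": gelu,
    "relu": relu,
    "tanh": tanh,
    "sigmoid": sigmoid,
    "identity": identity,
}


def maximum(a, c: float):
    """Elementwise max with a scalar constant (sub-gradient 0 at the kink)."""
    if not _is_t(a):
        return np.maximum(np.asarray(a), c)
    return add(relu(add(a, -c)), c)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    if not _is_t(a):
        return np.asarray(a).sum(axis=axis, keepdims=keepdims)
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        if not keepdims and axis is not None:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.data.shape))

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    if not _is_t(a):
        return np.asarray(a).mean(axis=axis, keepdims=keepdims)
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tmax(a, axis=None, keepdims=False):
    if not _is_t(a):
        return np.asarray(a).max(axis=axis, keepdims=keepdims)
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        full = out_data
        if not keepdims and axis is not None:
            gg = np.expand_dims(gg, axis)
            full = np.expand_dims(out_data, axis)
        mask = (a.data == full).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        _accum(a, mask * gg)

    return _node(out_data, (a,), backward)


def reshape(a, shape):
    if not _is_t(a):
        return np.asarray(a).reshape(shape)
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        _accum(a, np.asarray(g).reshape(a.data.shape))

    return _node(out_data, (a,), backward)


def transpose(a, axes):
    if not _is_t(a):
        return np.asarray(a).transpose(axes)
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, np.asarray(g).transpose(inv))

    return _node(out_data, (a,), backward)


def _getitem(a, idx):
    if not _is_t(a):
        return np.asarray(a)[idx]
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        _accum(a, buf)

    return _node(out_data, (a,), backward)


def concatenate(parts: Sequence, axis=0):
    if not _is_t(*parts):
        return np.concatenate([np.asarray(p) for p in parts], axis=axis)
    parts = [as_tensor(p) for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]

    def backward(g):
        start = 0
        for p, s in zip(parts, sizes):
            sl = [slice(None)] * out_data.ndim
            sl[axis] = slice(start, start + s)
            _accum(p, np.asarray(g)[tuple(sl)])
            start += s

    return _node(out_data, tuple(parts), backward)


def matmul(a, b):
    if not _is_t(a, b):
        return np.asarray(a) @ np.asarray(b)
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        g = np.asarray(g)
        _accum(a, g @ np.swapaxes(b.data, -1, -2))
        _accum(b, np.swapaxes(a.data, -1, -2) @ g)

    return _node(out_data, (a, b), backward)


def softmax(a, axis=-1):
    """Numerically stable softmax (max-shift is treated as a constant)."""
    if not _is_t(a):
        x = np.asarray(a, dtype=np.float64)
        x = x - x.max(axis=axis, keepdims=True)
        e = np.exp(x)
        return e / e.sum(axis=axis, keepdims=True)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(a - shift)
    return e / tsum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# DCT-diagonal spectral filter (custom primitive)
# ---------------------------------------------------------------------------

def dct_filter(x, weights):
    """``IDCT2( DCT2(x) * weights )`` over the trailing two axes.

    Uses the orthonormal DCT-II / DCT-III pair, i.e. multiplication by a
    diagonal operator in the Neumann (reflective-boundary) eigenbasis.  The
    operator is self-adjoint, so the input gradient is the same filter
    applied to the upstream gradient; the weight gradient is the product of
    the two spectra.
    """
    if not _is_t(x, weights):
        X = dctn(np.asarray(x, dtype=np.float64), axes=(-2, -1), norm="ortho")
        return idctn(X * np.asarray(weights), axes=(-2, -1), norm="ortho")
    x, weights = as_tensor(x), as_tensor(weights)
    X = dctn(x.data, axes=(-2, -1), norm="ortho")
    out_data = idctn(X * weights.data, axes=(-2, -1), norm="ortho")

    def backward(g):
        G = dctn(np.asarray(g), axes=(-2, -1), norm="ortho")
        _accum(x, idctn(G * weights.data, axes=(-2, -1), norm="ortho"))
        _accum(weights, X * G)

    return _node(out_data, (x, weights), backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Parameter container with recursive discovery, torch-free."""

    def parameters(self) -> list[Parameter]:
        out, seen = [], set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def set_group(self, group: str):
        for p in self.parameters():
            if p.group is None:
                p.group = group
        return self

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name → array mapping for checkpointing."""
        out = {}

        def walk(obj, prefix):
            if isinstance(obj, Parameter):
                out[prefix] = obj.data
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}[{i}]")

        walk(self, "")
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]):
        state = self.state_arrays()
        missing = set(state) ^ set(arrays)
        if missing:
            raise ValueError(f"checkpoint mismatch on keys: {sorted(missing)[:5]}")

        def walk(obj, prefix):
            if isinstance(obj, Parameter):
                obj.data = np.asarray(arrays[prefix],
                                      dtype=obj.data.dtype).reshape(obj.data.shape)
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}[{i}]")

        walk(self, "")
        return self


class Linear(Module):
    """Affine map ``x @ W + b`` with row-vector convention.

    ``init`` is one of ``"lecun"`` (fan-in scaled normal), ``"zero"``
    (identity-at-init residual heads), or ``"eye"`` (identity block).
    """

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init: str = "lecun", bias: bool = True):
        if init == "zero":
            w = np.zeros((in_features, out_features))
        elif init == "eye":
            w = np.eye(in_features, out_features)
        else:
            w = rng.normal(0.0, 1.0 / math.sqrt(in_features), (in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x):
        y = matmul(x, self.weight)
        return y if self.bias is None else add(y, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x):
        mu = tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = tmean(mul(xc, xc), axis=-1, keepdims=True)
        xn = xc / sqrt(var + self.eps)
        return add(mul(xn, self.gain), self.shift)


class AdamW:
    """AdamW with decoupled weight decay (applied to matrices only)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.1):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            if self.weight_decay and p.data.ndim >= 2:
                p.data = p.data - lr * self.weight_decay * p.data
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
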