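"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set needed by the sequence-to-track network:
broadcasting arithmetic, matmul/einsum, 1-D unfolding for convolutions,
reductions, softmax, GELU/ReLU/softplus, log/exp, slicing and reshaping.
Gradients are accumulated by a topological sweep over the recorded tape.

All arrays are kept in float64 by default; the engine is single-threaded and
fully deterministic, which the training-reproducibility contract relies on.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(data, np.ndarray) else data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None:
                continue
            node._backward(node.grad)

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad = self.grad + grad

    def zero_grad(self):
        self.grad = None

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take_slice(self, idx)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) != 1 or not isinstance(shape[0], tuple) else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def power(a, exponent):
    a = _wrap(a)
    out_data = a.data ** exponent

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1))

    return Tensor(out_data, parents=(a,), backward=bw)


def sqrt(a):
    return power(a, 0.5)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def einsum(spec, a, b):
    """Two-operand einsum.

    Restriction (met by every call site): no index repeats inside one operand,
    and each operand's indices are a subset of (output ∪ other operand).
    """
    a, b = _wrap(a), _wrap(b)
    ins, out = spec.split("->")
    sa, sb = ins.split(",")
    out_data = np.einsum(spec, a.data, b.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(np.einsum(f"{out},{sb}->{sa}", g, b.data))
        if b.requires_grad:
            b._accumulate(np.einsum(f"{out},{sa}->{sb}", g, a.data))

    return Tensor(out_data, parents=(a, b), backward=bw)


def exp(a):
    a = _wrap(a)
    out_data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor(out_data, parents=(a,), backward=bw)


def log(a):
    a = _wrap(a)
    out_data = np.log(a.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor(out_data, parents=(a,), backward=bw)


def reduce_sum(a, axis=None, keepdims=False):
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward=bw)


def reduce_mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(reduce_sum(a, axis, keepdims), 1.0 / n)


def reshape(a, shape):
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return Tensor(out_data, parents=(a,), backward=bw)


def transpose(a, axes):
    a = _wrap(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def bw(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    return Tensor(out_data, parents=(a,), backward=bw)


def take_slice(a, idx):
    a = _wrap(a)
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accumulate(buf)

    return Tensor(out_data, parents=(a,), backward=bw)


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def softmax(a, axis=-1):
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return Tensor(out_data, parents=(a,), backward=bw)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a):
    """Exact (erf) Gaussian error linear unit."""
    a = _wrap(a)
    cdf = 0.5 * (1.0 + _sp.erf(a.data * _INV_SQRT2))
    out_data = a.data * cdf

    def bw(g):
        if a.requires_grad:
            pdf = np.exp(-0.5 * a.data * a.data) * _INV_SQRT_2PI
            a._accumulate(g * (cdf + a.data * pdf))

    return Tensor(out_data, parents=(a,), backward=bw)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(out_data, parents=(a,), backward=bw)


def softplus(a):
    """log(1 + exp(x)), numerically stable; derivative is the logistic."""
    a = _wrap(a)
    out_data = np.logaddexp(0.0, a.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * _sp.expit(a.data))

    return Tensor(out_data, parents=(a,), backward=bw)


def unfold1d(a, kernel):
    """Extract sliding windows for a same-padded 1-D convolution.

    Input (B, L, C) -> output (B, L, kernel*C); odd kernel sizes only.
    """
    a = _wrap(a)
    if kernel % 2 != 1:
        raise ValueError("unfold1d requires an odd kernel size")
    pad = kernel // 2
    B, L, C = a.data.shape
    padded = np.pad(a.data, ((0, 0), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(padded, kernel, axis=1)
    # win: (B, L, C, kernel) -> (B, L, kernel, C)
    out_data = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, kernel * C)

    def bw(g):
        if not a.requires_grad:
            return
        gk = g.reshape(B, L, kernel, C)
        buf = np.zeros((B, L + 2 * pad, C))
        for j in range(kernel):
            buf[:, j:j + L, :] += gk[:, :, j, :]
        a._accumulate(buf[:, pad:pad + L, :])

    return Tensor(out_data, parents=(a,), backward=bw)
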