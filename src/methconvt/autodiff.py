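"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: every operation builds a node that
records its parents and a closure computing parent gradients from the output
gradient.  ``backward`` walks the graph in reverse topological order and
leaves the accumulated gradient on *every* visited node, so gradients of
intermediate activations (needed by Grad-CAM++) are available without any
special "retain" machinery.

Only the operations the model needs are implemented; all arrays are float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "backward"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "parents", "grad_fn", "grad")

    def __init__(self, data, parents=(), grad_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.grad_fn = grad_fn
        self.grad = None

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))
        out.grad_fn = lambda g: (
            _unbroadcast(g, self.shape),
            _unbroadcast(g, other.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out.grad_fn = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))
        out.grad_fn = lambda g: (
            _unbroadcast(g * other.data, self.shape),
            _unbroadcast(g * self.data, other.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))
        out.grad_fn = lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / other.data**2, other.shape),
        )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))
        out.grad_fn = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def grad_fn(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            if a.ndim == 1:  # (k,) @ (k, n)
                return g @ np.swapaxes(b, -1, -2), np.outer(a, g)
            if b.ndim == 1:  # (..., m, k) @ (k,)
                ga = g[..., None] * b
                gb = np.swapaxes(a, -1, -2) @ g[..., None]
                return _unbroadcast(ga, a.shape), _unbroadcast(gb[..., 0], b.shape)
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        out.grad_fn = grad_fn
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def grad_fn(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        out.grad_fn = grad_fn
        return out

    # -- shape ops ----------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out.grad_fn = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), (self,))
        out.grad_fn = lambda g: (g.transpose(*inv),)
        return out

    # -- reductions ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def grad_fn(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out.grad_fn = grad_fn
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out.grad_fn = lambda g: (g * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out.grad_fn = lambda g: (g / self.data,)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out.grad_fn = lambda g: (g * (self.data > 0),)
        return out

    def gelu(self):
        """Exact Gaussian-error-linear unit x * Phi(x)."""
        phi = 0.5 * (1.0 + erf(self.data * _INV_SQRT2))
        out = Tensor(self.data * phi, (self,))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * self.data**2)
        out.grad_fn = lambda g: (g * (phi + self.data * pdf),)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out.grad_fn = lambda g: (g * (1.0 - out.data**2),)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out.grad_fn = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, (x,))
    out.grad_fn = lambda g: (s * (g - (g * s).sum(axis=axis, keepdims=True)),)
    return out


def log_softmax(x: Tensor, axis=-1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = Tensor(shifted - lse, (x,))
    s = np.exp(out.data)
    out.grad_fn = lambda g: (g - s * g.sum(axis=axis, keepdims=True),)
    return out


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution, stride 1, zero 'same' padding.

    x: (B, C_in, P), w: (C_out, C_in, K) with K odd, b: (C_out,).
    Returns (B, C_out, P).
    """
    k = w.shape[-1]
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)  # (B, C_in, P, K)
    out_data = np.einsum("bipk,oik->bop", win, w.data, optimize=True)
    out_data += b.data[None, :, None]
    out = Tensor(out_data, (x, w, b))
    p_len = x.shape[2]

    def grad_fn(g):
        gw = np.einsum("bipk,bop->oik", win, g, optimize=True)
        gb = g.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        for j in range(k):
            gxp[:, :, j : j + p_len] += np.einsum(
                "bop,oi->bip", g, w.data[:, :, j], optimize=True
            )
        gx = gxp[:, :, pad : pad + p_len]
        return gx, gw, gb

    out.grad_fn = grad_fn
    return out


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along the last axis (tail truncated)."""
    b, c, p = x.shape
    lp = p // pool
    blocks = x.data[:, :, : lp * pool].reshape(b, c, lp, pool)
    arg = blocks.argmax(axis=-1)
    out = Tensor(blocks.max(axis=-1), (x,))

    def grad_fn(g):
        gb = np.zeros((b, c, lp, pool))
        np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : lp * pool] = gb.reshape(b, c, lp * pool)
        return (gx,)

    out.grad_fn = grad_fn
    return out


def take_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: rows `idx` of a 2-D table."""
    idx = np.asarray(idx)
    out = Tensor(table.data[idx], (table,))

    def grad_fn(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, idx, g)
        return (gt,)

    out.grad_fn = grad_fn
    return out


def gather_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather along the last axis with per-row indices (np.take_along_axis)."""
    out = Tensor(np.take_along_axis(x.data, idx, axis=-1), (x,))

    def grad_fn(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=-1)
        return (gx,)

    out.grad_fn = grad_fn
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0.0:
        return x
    keep = rng.random(x.shape) >= rate
    scale = 1.0 / (1.0 - rate)
    mask = keep * scale
    out = Tensor(x.data * mask, (x,))
    out.grad_fn = lambda g: (g * mask,)
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis (composed from primitives)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return xc * inv * gain + bias


def backward(out: Tensor, grad: np.ndarray | None = None) -> None:
    """Backpropagate from `out`, leaving .grad on every node in its graph."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(out, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))

    for node in topo:
        node.grad = None
    out.grad = np.ones_like(out.data) if grad is None else np.asarray(grad, float)

    for node in reversed(topo):
        if node.grad_fn is None or node.grad is None:
            continue
        grads = node.grad_fn(node.grad)
        for parent, g in zip(node.parents, grads):
            if g is None:
                continue
            if parent.grad is None:
                parent.grad = np.zeros_like(parent.data)
            parent.grad += g
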