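"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations needed by the sequence models in this
package (embedding lookup, batched matmul, masked softmax attention,
layer normalisation, masked mean pooling, gated recurrences) plus a
numerically stable binary cross-entropy head. Gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=True):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = parents
        self.bwd = bwd  # callable(out_grad) applied during backprop
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node.bwd is not None and node.grad is not None:
                node.bwd(node.grad)

    # convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _accum(t: Tensor, g: np.ndarray, own: bool = False) -> None:
    """Accumulate gradient into t; ``own=True`` means g is not aliased
    elsewhere (fresh array or a view disjoint from every other parent's
    share) and may be adopted without copying."""
    if not t.requires_grad:
        return
    g2 = _unbroadcast(g, t.data.shape)
    if t.grad is None:
        t.grad = g2 if (own or g2 is not g) else g2.copy()
    else:
        t.grad += g2


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x), requires_grad=False)


# ---------------------------------------------------------------- arithmetic
def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, (a, b))
    # b first: once a adopts g, further in-place use would alias
    out.bwd = lambda g: (_accum(b, g), _accum(a, g, own=True))
    return out


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data - b.data, (a, b))
    out.bwd = lambda g: (_accum(b, -g, own=True), _accum(a, g, own=True))
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, (a, b))
    out.bwd = lambda g: (_accum(a, g * b.data, own=True),
                         _accum(b, g * a.data, own=True))
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, (a,))
    out.bwd = lambda g: _accum(a, g * s, own=True)
    return out


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, (a, b))

    def bwd(g):
        _accum(a, g @ np.swapaxes(b.data, -1, -2), own=True)
        _accum(b, np.swapaxes(a.data, -1, -2) @ g, own=True)

    out.bwd = bwd
    return out


# ------------------------------------------------------------- shape plumbing
def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    out = Tensor(a.data.reshape(shape), (a,))
    out.bwd = lambda g: _accum(a, g.reshape(orig), own=True)
    return out


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    out = Tensor(a.data.transpose(axes), (a,))
    out.bwd = lambda g: _accum(a, np.ascontiguousarray(g.transpose(inv)), own=True)
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece, own=True)  # disjoint views

    out.bwd = bwd
    return out


def slice_axis1(a: Tensor, t: int) -> Tensor:
    """x[:, t, :] for a (B, L, D) tensor."""
    out = Tensor(a.data[:, t, :], (a,))

    def bwd(g):
        full = np.zeros_like(a.data)
        full[:, t, :] = g
        _accum(a, full, own=True)

    out.bwd = bwd
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out = Tensor(weight.data[idx], (weight,))

    def bwd(g):
        if not weight.requires_grad:
            return
        if idx.size > 2048:
            # bincount scatter: much faster than np.add.at for large batches
            gf = g.reshape(-1, g.shape[-1])
            idxf = idx.ravel()
            nv = weight.data.shape[0]
            acc = np.empty_like(weight.data)
            for j in range(gf.shape[1]):
                acc[:, j] = np.bincount(idxf, weights=gf[:, j], minlength=nv)
        else:
            acc = np.zeros_like(weight.data)
            np.add.at(acc, idx, g)
        _accum(weight, acc, own=True)

    out.bwd = bwd
    return out


# ----------------------------------------------------------------- nonlinear
def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0), (a,))
    out.bwd = lambda g: _accum(a, g * (a.data > 0), own=True)
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, (a,))
    out.bwd = lambda g: _accum(a, g * (1 - y * y), own=True)
    return out


def sigmoid(a: Tensor) -> Tensor:
    y = _sigmoid_np(a.data)
    out = Tensor(y, (a,))
    out.bwd = lambda g: _accum(a, g * y * (1 - y), own=True)
    return out


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(a: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis, with an optional additive (mask) term."""
    z = a.data if additive_mask is None else a.data + additive_mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, (a,))

    def bwd(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        _accum(a, (g - dot) * y, own=True)

    out.bwd = bwd
    return out


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, (a, gamma, beta))
    n = a.data.shape[-1]

    def bwd(g):
        _accum(gamma, g * xhat, own=True)
        _accum(beta, g)  # unbroadcast sums to (d,), so a fresh array
        gx = g * gamma.data
        # standard layer-norm backward over the last axis
        da = inv * (
            gx
            - gx.mean(axis=-1, keepdims=True)
            - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        )
        _accum(a, da, own=True)

    out.bwd = bwd
    return out


def masked_mean(a: Tensor, mask: np.ndarray) -> Tensor:
    """Mean of a (B, L, D) tensor over axis 1, restricted to mask==True.

    All-masked rows (patients with no events) pool to a zero vector.
    """
    m = mask.astype(a.data.dtype)[:, :, None]
    cnt = np.maximum(m.sum(axis=1), 1.0)  # (B, 1)
    out = Tensor((a.data * m).sum(axis=1) / cnt, (a,))
    out.bwd = lambda g: _accum(a, g[:, None, :] * m / cnt[:, None, :], own=True)
    return out


def dropout(a: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0:
        return a
    keep = (rng.random(a.data.shape) >= p).astype(a.data.dtype) / (1.0 - p)
    out = Tensor(a.data * keep, (a,))
    out.bwd = lambda g: _accum(a, g * keep, own=True)
    return out


def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable in the logits."""
    z = logits.data
    y = np.asarray(y, dtype=z.dtype).reshape(z.shape)
    loss = np.logaddexp(0.0, z) - y * z
    out = Tensor(np.array(loss.mean(), dtype=z.dtype), (logits,))
    out.bwd = lambda g: _accum(logits, g * (_sigmoid_np(z) - y) / z.size, own=True)
    return out


# ------------------------------------------------------------------ training
class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return add(matmul(x, w), b)


class Adam:
    """Adam optimiser over a flat list of Parameters."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
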