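"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation networks in :mod:`dsca.nets` need only a handful of
differentiable primitives: 2-D convolution with "same" padding, 2x2
max-pooling, 2x2 stride-2 transposed convolution, ReLU, sigmoid,
element-wise add/multiply (with broadcasting), channel concatenation and a
pixel-weighted binary cross-entropy head.  This module implements exactly
those on float32 arrays in channels-last (NHWC) layout, with a tape-based
backward pass.

Convolutions are realised as shift-and-matmul: for each kernel offset a
contiguous copy of the shifted, padded input feeds one GEMM.  On a single
CPU this keeps memory access sequential and the arithmetic inside BLAS,
which is what makes desk-scale training tractable without a deep-learning
framework.
"""

from __future__ import annotations

import numpy as np

#: Working dtype; float32 for speed, switchable to float64 for
#: high-precision verification.
DTYPE = np.float32

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "weighted_bce_with_logits",
    "Adam",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self):
        """Run reverse-mode accumulation from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0).astype(DTYPE)

    def backward(g):
        x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def _logistic(z: np.ndarray) -> np.ndarray:
    # stable on both tails
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    out_data = _logistic(x.data)

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors, axis=-1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same'-padded stride-1 cross-correlation in NHWC.

    ``x`` is (N, H, W, C); ``w`` is (kh, kw, C, O); ``b`` is (O,).
    """
    n, h, wd, c = x.data.shape
    kh, kw, c2, o = w.data.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    else:
        xp = x.data
    out = np.empty((n * h * wd, o), dtype=DTYPE)
    out[:] = b.data
    for i in range(kh):
        for j in range(kw):
            patch = np.ascontiguousarray(xp[:, i:i + h, j:j + wd, :]).reshape(n * h * wd, c)
            out += patch @ w.data[i, j]
    out_data = out.reshape(n, h, wd, o)

    def backward(g):
        gmat = g.reshape(n * h * wd, o)
        need_x = x.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        for i in range(kh):
            for j in range(kw):
                patch = np.ascontiguousarray(xp[:, i:i + h, j:j + wd, :]).reshape(n * h * wd, c)
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[i, j] += patch.T @ gmat
                if need_x:
                    gxp[:, i:i + h, j:j + wd, :] += (gmat @ w.data[i, j].T).reshape(n, h, wd, c)
        if b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if need_x:
            x._accumulate(gxp[:, ph:ph + h, pw:pw + wd, :] if (ph or pw) else gxp)

    return Tensor(out_data, parents=(x, w, b), backward=backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-2 2x2 transposed convolution (learned 2x upsampling) in NHWC.

    ``w`` has shape (2, 2, C_in, C_out); output spatial dims double.
    """
    n, h, wd, c = x.data.shape
    kh, kw, c2, o = w.data.shape
    if c != c2:
        raise ValueError(f"conv_transpose channel mismatch: input {c}, weight {c2}")
    xmat = x.data.reshape(n * h * wd, c)
    out_data = np.empty((n, h, kh, wd, kw, o), dtype=DTYPE)
    for a in range(kh):
        for bb in range(kw):
            out_data[:, :, a, :, bb, :] = (xmat @ w.data[a, bb]).reshape(n, h, wd, o)
    out_data = out_data.reshape(n, h * kh, wd * kw, o) + b.data

    def backward(g):
        gr = g.reshape(n, h, kh, wd, kw, o)
        gx = np.zeros((n * h * wd, c), dtype=DTYPE) if x.requires_grad else None
        for a in range(kh):
            for bb in range(kw):
                gslot = np.ascontiguousarray(gr[:, :, a, :, bb, :]).reshape(n * h * wd, o)
                if w.requires_grad:
                    w.grad = np.zeros_like(w.data) if w.grad is None else w.grad
                    w.grad[a, bb] += xmat.T @ gslot
                if gx is not None:
                    gx += gslot @ w.data[a, bb].T
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if gx is not None:
            x._accumulate(gx.reshape(n, h, wd, c))

    return Tensor(out_data, parents=(x, w, b), backward=backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    quads = (x.data[:, 0::2, 0::2, :], x.data[:, 0::2, 1::2, :],
             x.data[:, 1::2, 0::2, :], x.data[:, 1::2, 1::2, :])
    out_data = np.maximum(np.maximum(quads[0], quads[1]),
                          np.maximum(quads[2], quads[3]))

    def backward(g):
        gx = np.zeros_like(x.data)
        taken = np.zeros(out_data.shape, dtype=bool)
        views = (gx[:, 0::2, 0::2, :], gx[:, 0::2, 1::2, :],
                 gx[:, 1::2, 0::2, :], gx[:, 1::2, 1::2, :])
        # first quadrant attaining the max receives the gradient
        for q, view in zip(quads, views):
            hit = (q == out_data) & ~taken
            view[hit] = g[hit]
            taken |= hit
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def weighted_bce_with_logits(z: Tensor, y: np.ndarray, w_pos: float, w_neg: float) -> Tensor:
    """Mean class-weighted binary cross-entropy from logits.

    Equivalent to applying a sigmoid and the probability-space weighted BCE,
    but computed via log-add-exp so neither tail overflows.
    """
    y = np.asarray(y, dtype=np.float32)
    zd = z.data
    softplus_neg = np.logaddexp(0.0, -zd)   # -log sigmoid(z)
    softplus_pos = np.logaddexp(0.0, zd)    # -log (1 - sigmoid(z))
    per_pix = w_pos * y * softplus_neg + w_neg * (1.0 - y) * softplus_pos
    out_data = DTYPE(per_pix.mean())
    n = zd.size

    def backward(g):
        s = _logistic(zd)
        dz = (w_pos * y * (s - 1.0) + w_neg * (1.0 - y) * s) / n
        z._accumulate(np.asarray(g, dtype=DTYPE) * dz.astype(DTYPE))

    return Tensor(out_data, parents=(z,), backward=backward)


class Adam:
    """Adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
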