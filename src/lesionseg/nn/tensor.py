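"""Minimal reverse-mode autodiff on NumPy arrays.

Everything here works on NCHW-ordered float arrays.  Convolutions are
"same"-padded, stride-1 cross-correlations implemented as im2col matrix
products so the heavy lifting lands in BLAS; their input gradients are
themselves expressed as correlations with the flipped kernel, which keeps
the backward pass at matrix-multiplication speed as well.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "dropout",
    "maxpool2d",
    "maxpool_same",
    "relu",
    "sigmoid",
    "swish",
    "upsample_zeros",
]


class Tensor:
    """An ndarray plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, prev=(), requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in prev)
        self._prev = tuple(prev)
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar or array) tensor with seed grad 1."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _same_windows(x, k, dilation):
    """Sliding k-tap dilated windows of a same-padded NCHW array.

    Returns a strided view of shape (B, C, H, W, k, k); no data is copied.
    """
    ke = dilation * (k - 1) + 1
    p = (ke - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (ke, ke), axis=(2, 3))
    return win[..., ::dilation, ::dilation]


def _pad_same(x, k, dilation):
    ke = dilation * (k - 1) + 1
    p = (ke - 1) // 2
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _tap_views(xp, k, dilation, H, W):
    """Contiguous copies of the k*k shifted slices, flattened to (B, M, H*W)."""
    for di in range(k):
        for dj in range(k):
            v = xp[:, :, di * dilation : di * dilation + H,
                   dj * dilation : dj * dilation + W]
            yield di, dj, np.ascontiguousarray(v).reshape(v.shape[0], v.shape[1], -1)


def _conv2d_raw(x, w, dilation=1):
    """Same-padded stride-1 cross-correlation; x: (B,M,H,W), w: (N,M,k,k).

    Computed as one GEMM per kernel tap over shifted input slices; this
    keeps memory access sequential and the arithmetic inside BLAS.
    """
    B, M, H, W = x.shape
    N, _, k, _ = w.shape
    xp = _pad_same(x, k, dilation)
    acc = None
    for di, dj, v in _tap_views(xp, k, dilation, H, W):
        term = np.matmul(w[:, :, di, dj], v)  # (N,M) @ (B,M,HW) -> (B,N,HW)
        acc = term if acc is None else acc + term
    return acc.reshape(B, N, H, W)


def _flip_T(w):
    # kernel for the input-gradient correlation: 180 deg flip, channels swapped
    return np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))


def conv2d(x: Tensor, w: Tensor, dilation: int = 1) -> Tensor:
    out = Tensor(_conv2d_raw(x.data, w.data, dilation), prev=(x, w))

    def _backward(gy):
        B, M, H, W = x.data.shape
        N, _, k, _ = w.data.shape
        if w.requires_grad:
            gy2 = gy.reshape(B, N, H * W)
            gw = np.empty_like(w.data)
            xp = _pad_same(x.data, k, dilation)
            for di, dj, v in _tap_views(xp, k, dilation, H, W):
                gw[:, :, di, dj] = np.matmul(gy2, v.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw)
        if x.requires_grad:
            x._accumulate(_conv2d_raw(gy, _flip_T(w.data), dilation))

    out._backward = _backward
    return out


def depthwise_conv2d(x: Tensor, w: Tensor) -> Tensor:
    """Per-channel 2-D correlation; w has shape (M, k, k)."""
    k = w.data.shape[-1]
    win = _same_windows(x.data, k, 1)
    out = Tensor(
        np.einsum("bmhwij,mij->bmhw", win, w.data, optimize=True), prev=(x, w)
    )

    def _backward(gy):
        if w.requires_grad:
            win_b = _same_windows(x.data, k, 1)
            w._accumulate(np.einsum("bmhwij,bmhw->mij", win_b, gy, optimize=True))
        if x.requires_grad:
            gwin = _same_windows(gy, k, 1)
            wf = w.data[:, ::-1, ::-1]
            x._accumulate(np.einsum("bmhwij,mij->bmhw", gwin, wf, optimize=True))

    out._backward = _backward
    return out


def upsample_zeros(x: Tensor, stride: int) -> Tensor:
    """Insert stride-1 zeros between pixels (the expand step of a transposed conv)."""
    B, C, H, W = x.data.shape
    z = np.zeros((B, C, H * stride, W * stride), dtype=x.data.dtype)
    z[:, :, ::stride, ::stride] = x.data
    out = Tensor(z, prev=(x,))

    def _backward(gy):
        if x.requires_grad:
            x._accumulate(gy[:, :, ::stride, ::stride])

    out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    B, C, H, W = x.data.shape
    Ho, Wo = H // size, W // size
    xr = x.data.reshape(B, C, Ho, size, Wo, size).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(B, C, Ho, Wo, size * size)
    idx = flat.argmax(-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], -1)[..., 0], prev=(x,))

    def _backward(gy):
        if x.requires_grad:
            g = np.zeros((B, C, Ho, Wo, size * size), dtype=gy.dtype)
            np.put_along_axis(g, idx[..., None], gy[..., None], -1)
            g = g.reshape(B, C, Ho, Wo, size, size).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(g.reshape(B, C, H, W))

    out._backward = _backward
    return out


def maxpool_same(x: Tensor, size: int = 3) -> Tensor:
    """Stride-1 max pooling with "same" output size (pads with -inf)."""
    B, C, H, W = x.data.shape
    p = (size - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    win = sliding_window_view(xp, (size, size), axis=(2, 3))
    flat = win.reshape(B, C, H, W, size * size)
    idx = flat.argmax(-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], -1)[..., 0], prev=(x,))

    def _backward(gy):
        if not x.requires_grad:
            return
        gp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=gy.dtype)
        bi, ci, ii, jj = np.indices((B, C, H, W), sparse=True)
        np.add.at(gp, (bi, ci, ii + idx // size, jj + idx % size), gy)
        x._accumulate(gp[:, :, p : p + H, p : p + W])

    out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# pointwise ops
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(gy):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * gy.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(gy[tuple(sl)])

    out._backward = _backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, prev=(a, b))

    def _backward(gy):
        if a.requires_grad:
            a._accumulate(gy)
        if b.requires_grad:
            b._accumulate(gy)

    out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), prev=(x,))

    def _backward(gy):
        if x.requires_grad:
            x._accumulate(gy * (x.data > 0))

    out._backward = _backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, prev=(x,))

    def _backward(gy):
        if x.requires_grad:
            x._accumulate(gy * s * (1.0 - s))

    out._backward = _backward
    return out


def swish(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    f = x.data * s
    out = Tensor(f, prev=(x,))

    def _backward(gy):
        if x.requires_grad:
            # closed-form derivative: f(x) + sigma(x) * (1 - f(x))
            x._accumulate(gy * (f + s * (1.0 - f)))

    out._backward = _backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
    out = Tensor(x.data * mask, prev=(x,))

    def _backward(gy):
        if x.requires_grad:
            x._accumulate(gy * mask)

    out._backward = _backward
    return out
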