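"""Convolution, pooling and resampling primitives with custom gradients.

Convolutions are computed by lowering each input window into a column matrix
(im2col) and dispatching the contraction to BLAS.  The scatter-add col2im is
the exact adjoint of im2col, which is what makes transposed convolution and
the input gradient of convolution the same primitive.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "avg_pool2d",
    "interpolate_bilinear",
]


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """Lower padded input (N,C,Hp,Wp) to columns (N, C*kh*kw, Ho*Wo)."""
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols, out_shape, kh, kw, stride, dilation, ho, wo):
    """Adjoint of :func:`_im2col`: scatter-add columns back to (N,C,Hp,Wp)."""
    n, c, hp, wp = out_shape
    x = np.zeros(out_shape, dtype=np.float32)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            x[:, :, hi : hi + stride * ho : stride, wj : wj + stride * wo : stride] += cols[:, :, i, j]
    return x


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation of ``x`` (N,C,H,W) with ``weight`` (O,C,kh,kw)."""
    o, c, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(
            f"conv2d: input has {x.shape[1]} channels, weight expects {c}"
        )
    xp = _pad(x.data, padding)
    cols, ho, wo = _im2col(xp, kh, kw, stride, dilation)
    n = x.shape[0]
    w2 = weight.data.reshape(o, c * kh * kw)
    out = np.matmul(w2, cols).reshape(n, o, ho, wo)
    if bias is not None:
        out += bias.data.reshape(1, o, 1, 1)
    pad_shape = xp.shape

    def backward(g):
        gf = g.reshape(n, o, ho * wo)
        if weight.requires_grad:
            gw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(w2.T, gf)
            gxp = _col2im(gcols, pad_shape, kh, kw, stride, dilation, ho, wo)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Transposed convolution; ``weight`` is (C_in, C_out, kh, kw).

    Output size is ``(H-1)*stride + kh - 2*padding`` per spatial axis — the
    inverse of the corresponding strided convolution's size arithmetic.
    """
    c_in, c_out, kh, kw = weight.shape
    if x.shape[1] != c_in:
        raise ValueError(
            f"conv_transpose2d: input has {x.shape[1]} channels, expected {c_in}"
        )
    n, _, h, w = x.shape
    hp = (h - 1) * stride + kh
    wp = (w - 1) * stride + kw
    w2 = weight.data.reshape(c_in, c_out * kh * kw)
    xf = x.data.reshape(n, c_in, h * w)
    cols = np.matmul(w2.T, xf)
    out = _col2im(cols, (n, c_out, hp, wp), kh, kw, stride, 1, h, w)
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    if bias is not None:
        out += bias.data.reshape(1, c_out, 1, 1)

    def backward(g):
        gp = _pad(g, padding)
        gcols, gh, gw_ = _im2col(gp, kh, kw, stride, 1)
        # forward lowered x through W2.T then scattered; adjoint gathers then W2
        if x.requires_grad:
            gx = np.matmul(w2, gcols).reshape(x.shape)
            x._accumulate(gx)
        if weight.requires_grad:
            gw2 = np.matmul(xf, gcols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw2.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    """Max pooling with window ``kernel`` and the given stride (default = kernel)."""
    stride = kernel if stride is None else stride
    n, c, h, w = x.shape
    if kernel > h + 2 * padding or kernel > w + 2 * padding:
        raise ValueError(
            f"max_pool2d: window {kernel} exceeds spatial extent {(h, w)}"
        )
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                    constant_values=-np.inf)
    else:
        xp = x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    pad_h, pad_w = xp.shape[2], xp.shape[3]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros((n, c, pad_h, pad_w), dtype=np.float32)
        oh = np.arange(ho)[:, None] * stride
        ow = np.arange(wo)[None, :] * stride
        rows = np.broadcast_to(oh + idx // kernel, idx.shape)
        colz = np.broadcast_to(ow + idx % kernel, idx.shape)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (ni, ci, rows, colz), g)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def avg_pool2d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping average pooling (stride = kernel); extent must divide."""
    n, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError(f"avg_pool2d: {kernel} does not divide extent {(h, w)}")
    ho, wo = h // kernel, w // kernel
    out = x.data.reshape(n, c, ho, kernel, wo, kernel).mean(axis=(3, 5))
    inv = 1.0 / (kernel * kernel)

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3) * inv
            x._accumulate(gx)

    return Tensor._make(out.astype(np.float32), (x,), backward)


def _linear_interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D linear interpolation matrix (align-corners)."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


def interpolate_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of (N,C,H,W) to ``size`` via separable interpolation."""
    ho, wo = size
    _, _, h, w = x.shape
    ar = _linear_interp_matrix(ho, h)
    ac = _linear_interp_matrix(wo, w)
    out = np.einsum("oh,nchw,pw->ncop", ar, x.data, ac, optimize=True)

    def backward(g):
        if x.requires_grad:
            gx = np.einsum("oh,ncop,pw->nchw", ar, g, ac, optimize=True)
            x._accumulate(gx.astype(np.float32))

    return Tensor._make(out.astype(np.float32), (x,), backward)
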