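"""Structured NN operations (convolutions, pooling, upsampling) on Tensors.

Convolutions are computed by explicit patch extraction (im2col) and einsum;
their adjoints reuse the same primitives, so forward and backward share one
code path.  All spatial operators take NCHW tensors.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "upsample_nearest2x",
    "global_avg_pool",
]


def _out_size(size: int, k: int, stride: int, pad: int, dil: int) -> int:
    return (size + 2 * pad - dil * (k - 1) - 1) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dil: int) -> np.ndarray:
    """(N,C,H,W) -> (N,C,kh,kw,Ho,Wo) patch view (copied)."""
    n, c, h, w = x.shape
    ho = _out_size(h, kh, stride, pad, dil)
    wo = _out_size(w, kw, stride, pad, dil)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[
                :, :, i * dil : i * dil + stride * ho : stride, j * dil : j * dil + stride * wo : stride
            ]
    return cols


def _col2im(cols: np.ndarray, hw: tuple[int, int], stride: int, pad: int, dil: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (N,C,H,W)."""
    n, c, kh, kw, ho, wo = cols.shape
    h, w = hw
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i * dil : i * dil + stride * ho : stride, j * dil : j * dil + stride * wo : stride] += cols[
                :, :, i, j
            ]
    return out[:, :, pad : pad + h, pad : pad + w] if pad else out


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """Grouped 2D convolution.  ``weight`` is (O, C//groups, kh, kw)."""
    n, c, h, w = x.shape
    o, cg, kh, kw = weight.shape
    if c != cg * groups:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cg * groups}")
    ho = _out_size(h, kh, stride, padding, dilation)
    wo = _out_size(w, kw, stride, padding, dilation)
    og = o // groups

    cols = _im2col(x.data, kh, kw, stride, padding, dilation)  # (N,C,kh,kw,Ho,Wo)
    kk = kh * kw
    if groups == 1:
        cols_m = cols.reshape(n, c * kk, ho * wo)
        w_m = weight.data.reshape(o, c * kk)
        out = np.matmul(w_m, cols_m).reshape(n, o, ho, wo)
    elif groups == c and cg == 1:  # depthwise
        cols_d = cols.reshape(n, c, kk, ho * wo)
        out = (cols_d * weight.data.reshape(1, c, kk, 1)).sum(axis=2).reshape(n, o, ho, wo)
    else:
        cols_g = cols.reshape(n, groups, cg * kk, ho * wo)
        w_g = weight.data.reshape(groups, og, cg * kk)
        out = np.einsum("gok,ngkl->ngol", w_g, cols_g, optimize=True).reshape(n, o, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if groups == 1:
            g_m = g.reshape(n, o, ho * wo)
            cols_m = cols.reshape(n, c * kk, ho * wo)
            if weight.requires_grad:
                dw = np.matmul(g_m, cols_m.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(dw.reshape(o, cg, kh, kw))
            if x.requires_grad:
                w_m = weight.data.reshape(o, c * kk)
                dcols = np.matmul(w_m.T, g_m)
                dx = _col2im(dcols.reshape(n, c, kh, kw, ho, wo), (h, w), stride, padding, dilation)
                x._accumulate(dx)
        elif groups == c and cg == 1:
            g_d = g.reshape(n, c, 1, ho * wo)
            cols_d = cols.reshape(n, c, kk, ho * wo)
            if weight.requires_grad:
                dw = (g_d * cols_d).sum(axis=(0, 3))
                weight._accumulate(dw.reshape(o, cg, kh, kw))
            if x.requires_grad:
                dcols = g_d * weight.data.reshape(1, c, kk, 1)
                dx = _col2im(dcols.reshape(n, c, kh, kw, ho, wo), (h, w), stride, padding, dilation)
                x._accumulate(dx)
        else:
            g_g = g.reshape(n, groups, og, ho * wo)
            cols_g = cols.reshape(n, groups, cg * kk, ho * wo)
            w_g = weight.data.reshape(groups, og, cg * kk)
            if weight.requires_grad:
                dw = np.einsum("ngol,ngkl->gok", g_g, cols_g, optimize=True)
                weight._accumulate(dw.reshape(o, cg, kh, kw))
            if x.requires_grad:
                dcols = np.einsum("gok,ngol->ngkl", w_g, g_g, optimize=True)
                dx = _col2im(dcols.reshape(n, c, kh, kw, ho, wo), (h, w), stride, padding, dilation)
                x._accumulate(dx)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, backward)


def conv_transpose2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 2,
    padding: int = 1,
) -> Tensor:
    """Transposed 2D convolution.  ``weight`` is (C_in, C_out, kh, kw).

    Output side = (H - 1) * stride - 2 * padding + kh.
    """
    n, ci, h, w = x.shape
    wci, co, kh, kw = weight.shape
    if ci != wci:
        raise ValueError(f"conv_transpose2d: input has {ci} channels, weight expects {wci}")
    ho = (h - 1) * stride - 2 * padding + kh
    wo = (w - 1) * stride - 2 * padding + kw

    cols = np.einsum("cdij,nchw->ndijhw", weight.data, x.data, optimize=True)
    out = _col2im(cols, (ho, wo), stride, padding, 1)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gcols = _im2col(g, kh, kw, stride, padding, 1)  # (N,Co,kh,kw,H,W)
        if x.requires_grad:
            dx = np.einsum("cdij,ndijhw->nchw", weight.data, gcols, optimize=True)
            x._accumulate(dx)
        if weight.requires_grad:
            dw = np.einsum("nchw,ndijhw->cdij", x.data, gcols, optimize=True)
            weight._accumulate(dw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    """Max pooling with square window; requires H, W divisible by the stride
    when kernel == stride (the only configuration the encoder uses)."""
    stride = stride or kernel
    if kernel != stride:
        raise NotImplementedError("max_pool2d supports kernel == stride")
    n, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError(f"max_pool2d: spatial size {h}x{w} not divisible by {kernel}")
    ho, wo = h // kernel, w // kernel
    windows = x.data.reshape(n, c, ho, kernel, wo, kernel).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, ho, wo, kernel, kernel)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(dx)

    return Tensor._make(out, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling; backward sums 2x2 blocks."""
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    return x.mean(axis=(2, 3))
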