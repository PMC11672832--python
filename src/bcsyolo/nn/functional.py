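"""Convolution, pooling and resampling primitives with hand-written gradients.

Convolution uses im2col + batched matrix multiply so the heavy lifting is
done by BLAS; the backward pass reuses the column buffer for the weight
gradient and scatters the input gradient with a small loop over kernel
offsets (col2im).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, is_grad_enabled

__all__ = ["conv2d", "max_pool2d", "upsample_nearest"]


def _col_view(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> view (N,C,Ho,Wo,kh,kw)."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation.

    x: (N, Cin, H, W); weight: (Cout, Cin/groups, kh, kw); bias: (Cout,).
    """
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {cin} channels, "
            f"weight expects {cin_g * groups} (groups={groups})")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    win = _col_view(xp, kh, kw, stride, stride)            # N,Cin,Ho,Wo,kh,kw
    # columns: (N, groups, Cg*kh*kw, Ho*Wo)
    col = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, groups, cin_g * kh * kw, ho * wo)
    wmat = weight.data.reshape(groups, cout // groups, cin_g * kh * kw)
    out = np.einsum("gok,ngkl->ngol", wmat, col, optimize=True)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = [p for p in (x, weight, bias) if p is not None]
    result = Tensor(out)
    if not (is_grad_enabled() and any(p.requires_grad for p in parents)):
        return result

    def backward(g):
        gy = g.reshape(n, groups, cout // groups, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", gy, col, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcol = np.einsum("gok,ngol->ngkl", wmat, gy, optimize=True)
            gcol = gcol.reshape(n, cin, kh, kw, ho, wo)
            hp, wp = h + 2 * padding, w + 2 * padding
            gxp = np.zeros((n, cin, hp, wp), dtype=g.dtype)
            for i in range(kh):
                hi = i + stride * ho
                for j in range(kw):
                    wj = j + stride * wo
                    gxp[:, :, i:hi:stride, j:wj:stride] += gcol[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    result.requires_grad = True
    result._prev = tuple(parents)
    result._backward = backward
    return result


def max_pool2d(x: Tensor, kernel_size: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    k = kernel_size
    s = stride or k
    n, c, h, w = x.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    ho = (h + 2 * padding - k) // s + 1
    wo = (w + 2 * padding - k) // s + 1
    win = _col_view(xp, k, k, s, s).reshape(n, c, ho, wo, k * k)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    result = Tensor(out)
    if not (is_grad_enabled() and x.requires_grad):
        return result

    def backward(g):
        hp, wp = h + 2 * padding, w + 2 * padding
        gxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
        ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = ii[None, None] * s + arg // k
        cols = jj[None, None] * s + arg % k
        nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(gxp, (nn_[..., None, None], cc[..., None, None], rows, cols), g)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accum(gxp)

    result.requires_grad = True
    result._prev = (x,)
    result._backward = backward
    return result


def upsample_nearest(x: Tensor, scale: int = 2) -> Tensor:
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)
    result = Tensor(out)
    if not (is_grad_enabled() and x.requires_grad):
        return result

    def backward(g):
        n, c, h2, w2 = g.shape
        gr = g.reshape(n, c, h2 // scale, scale, w2 // scale, scale).sum(axis=(3, 5))
        x._accum(gr)

    result.requires_grad = True
    result._prev = (x,)
    result._backward = backward
    return result
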