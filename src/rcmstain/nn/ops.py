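"""Differentiable array operations used by the network layers.

Convolutions are computed as an explicit sum over kernel offsets — at the
kernel sizes used here (3x3, 3x3x3, 2x2) this is a handful of large
``einsum`` calls per layer, which vectorizes well without an im2col copy.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation), NCHW layout.

    ``w`` has shape (out_ch, in_ch, kh, kw); ``padding`` pads H and W
    symmetrically with zeros.
    """
    n, c, h, wd = x.data.shape
    oc, ic, kh, kw = w.data.shape
    if ic != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ic}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2:]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    out = np.zeros((n, oc, ho, wo))
    for ky in range(kh):
        for kx in range(kw):
            sl = xp[:, :, ky:ky + stride * ho:stride, kx:kx + stride * wo:stride]
            out += np.einsum("oc,nchw->nohw", w.data[:, :, ky, kx], sl,
                             optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for ky in range(kh):
            for kx in range(kw):
                sl = xp[:, :, ky:ky + stride * ho:stride,
                        kx:kx + stride * wo:stride]
                gxp[:, :, ky:ky + stride * ho:stride,
                    kx:kx + stride * wo:stride] += np.einsum(
                    "oc,nohw->nchw", w.data[:, :, ky, kx], g, optimize=True)
                gw[:, :, ky, kx] = np.einsum("nohw,nchw->oc", g, sl,
                                             optimize=True)
        gx = gxp[:, :, padding:padding + h, padding:padding + wd] \
            if padding else gxp
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out, parents, backward)


def conv3d_depth_valid(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """3D convolution, NCDHW layout, 'valid' along depth and 'same' in H/W.

    Each application shrinks the depth dimension by (kd - 1); three stacked
    3x3x3 layers therefore collapse a 7-slice stack to a single slice.
    """
    n, c, d, h, wd = x.data.shape
    oc, ic, kd, kh, kw = w.data.shape
    if ic != c:
        raise ValueError(f"conv3d channel mismatch: input {c}, weight {ic}")
    if d < kd:
        raise ValueError(f"depth {d} smaller than kernel depth {kd}")
    py, px = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, 0), (py, py), (px, px)))
    do = d - kd + 1
    out = np.zeros((n, oc, do, h, wd))
    for kz in range(kd):
        for ky in range(kh):
            for kx in range(kw):
                sl = xp[:, :, kz:kz + do, ky:ky + h, kx:kx + wd]
                out += np.einsum("oc,ncdhw->nodhw", w.data[:, :, kz, ky, kx],
                                 sl, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None, None]

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for kz in range(kd):
            for ky in range(kh):
                for kx in range(kw):
                    sl = xp[:, :, kz:kz + do, ky:ky + h, kx:kx + wd]
                    gxp[:, :, kz:kz + do, ky:ky + h, kx:kx + wd] += np.einsum(
                        "oc,nodhw->ncdhw", w.data[:, :, kz, ky, kx], g,
                        optimize=True)
                    gw[:, :, kz, ky, kx] = np.einsum("nodhw,ncdhw->oc", g, sl,
                                                     optimize=True)
        gx = gxp[:, :, :, py:py + h, px:px + wd]
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3, 4))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out, parents, backward)


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (H, W must be even)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2d requires even spatial dimensions")
    out = 0.25 * (x.data[:, :, 0::2, 0::2] + x.data[:, :, 0::2, 1::2]
                  + x.data[:, :, 1::2, 0::2] + x.data[:, :, 1::2, 1::2])

    def backward(g):
        gx = np.zeros_like(x.data)
        for dy in (0, 1):
            for dx in (0, 1):
                gx[:, :, dy::2, dx::2] = 0.25 * g
        return ((x, gx),)

    return Tensor._result(out, (x,), backward)


_upsample_cache: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """Dense (2n, n) bilinear interpolation matrix (half-pixel centers)."""
    a = _upsample_cache.get(n)
    if a is None:
        a = np.zeros((2 * n, n))
        for j in range(2 * n):
            src = (j + 0.5) / 2.0 - 0.5
            src = min(max(src, 0.0), n - 1.0)
            i0 = int(np.floor(src))
            i1 = min(i0 + 1, n - 1)
            t = src - i0
            a[j, i0] += 1.0 - t
            a[j, i1] += t
        _upsample_cache[n] = a
    return a


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling (NCHW); exact transpose backward."""
    n, c, h, w = x.data.shape
    ah, aw = _upsample_matrix(h), _upsample_matrix(w)
    out = np.einsum("Hh,nchw,Ww->ncHW", ah, x.data, aw, optimize=True)

    def backward(g):
        return ((x, np.einsum("Hh,ncHW,Ww->nchw", ah, g, aw, optimize=True)),)

    return Tensor._result(out, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running: dict | None = None, training: bool = True,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over all axes except channel (axis 1)."""
    axes = tuple(a for a in range(x.data.ndim) if a != 1)
    shape = [1] * x.data.ndim
    shape[1] = x.data.shape[1]
    if training or running is None or "mean" not in running:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if running is not None:
            if "mean" not in running:
                running["mean"], running["var"] = mu.copy(), var.copy()
            else:
                running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
                running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    std = np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) / std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    m = x.data.size // x.data.shape[1]

    def backward(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        dxhat = g * gamma.data.reshape(shape)
        if training:
            gx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
                  - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
                  ) / std.reshape(shape)
        else:
            gx = dxhat / std.reshape(shape)
        return ((x, gx), (gamma, dgamma), (beta, dbeta))

    return Tensor._result(out, (x, gamma, beta), backward)


def flow_warp(image: np.ndarray, flow: Tensor) -> Tensor:
    """Warp `image` (N,C,H,W ndarray, constant) by `flow` (N,2,H,W Tensor).

    Pull semantics: output(y, x) samples image at (y + dy, x + dx) with
    bilinear interpolation and edge clamping.  Gradients flow to the flow
    field only; the sampled image is treated as data.
    """
    img = np.asarray(image, dtype=np.float64)
    n, c, h, w = img.shape
    dy, dx = flow.data[:, 0], flow.data[:, 1]
    gy, gx = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    ys_raw = gy[None] + dy
    xs_raw = gx[None] + dx
    ys = np.clip(ys_raw, 0, h - 1)
    xs = np.clip(xs_raw, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = ys - y0
    wx = xs - x0
    ni = np.arange(n)[:, None, None, None]
    ci = np.arange(c)[None, :, None, None]
    i00 = img[ni, ci, y0[:, None], x0[:, None]]
    i01 = img[ni, ci, y0[:, None], x1[:, None]]
    i10 = img[ni, ci, y1[:, None], x0[:, None]]
    i11 = img[ni, ci, y1[:, None], x1[:, None]]
    wyb, wxb = wy[:, None], wx[:, None]
    out = ((1 - wyb) * (1 - wxb) * i00 + (1 - wyb) * wxb * i01
           + wyb * (1 - wxb) * i10 + wyb * wxb * i11)
    # derivative masks: zero where the sample position was clamped
    my = ((ys_raw > 0) & (ys_raw < h - 1)).astype(np.float64)
    mx = ((xs_raw > 0) & (xs_raw < w - 1)).astype(np.float64)

    def backward(g):
        d_dy = ((1 - wxb) * (i10 - i00) + wxb * (i11 - i01))
        d_dx = ((1 - wyb) * (i01 - i00) + wyb * (i11 - i10))
        gf = np.zeros_like(flow.data)
        gf[:, 0] = (g * d_dy).sum(axis=1) * my
        gf[:, 1] = (g * d_dx).sum(axis=1) * mx
        return ((flow, gf),)

    return Tensor._result(out, (flow,), backward)
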