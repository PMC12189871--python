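"""Spatial autodiff primitives: convolution, pooling, up-sampling, batch norm.

All operations use NCHW layout.  Convolution is computed by the im2col /
GEMM route so the heavy lifting runs inside BLAS; its backward pass reuses
the stored patch matrix for the weight gradient and scatters the input
gradient with one vectorised slice-add per kernel tap.  Depth-wise
convolution (groups == channels) takes a dedicated einsum path because an
im2col matrix with one row per channel would be almost entirely zeros.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, as_tensor

__all__ = [
    "conv2d", "max_pool2d", "upsample_nearest", "batch_norm2d",
    "binary_cross_entropy_with_logits",
]


def _pad_input(x: np.ndarray, padding: int, value: float = 0.0) -> np.ndarray:
    if padding == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                  constant_values=value)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW, square kernel/stride/padding."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    cout, cin_g, k, _ = weight.shape
    n, cin, h, w = x.shape
    if cin != cin_g * groups:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cin_g * groups}")
    if groups == cin and cout == cin and cin_g == 1:
        return _conv2d_depthwise(x, weight, bias, stride, padding, dilation)
    if groups != 1:
        # split into per-group dense convolutions (rare path)
        outs = []
        cpg_in, cpg_out = cin // groups, cout // groups
        from .autograd import concat
        for g in range(groups):
            xg = x[:, g * cpg_in:(g + 1) * cpg_in]
            wg = weight[g * cpg_out:(g + 1) * cpg_out]
            bg = bias[g * cpg_out:(g + 1) * cpg_out] if bias is not None else None
            outs.append(conv2d(xg, wg, bg, stride=stride, padding=padding,
                               dilation=dilation))
        return concat(outs, axis=1)

    keff = (k - 1) * dilation + 1
    xp = _pad_input(x.data, padding)
    win = sliding_window_view(xp, (keff, keff), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # N,C,Ho,Wo,k,k
    n_, c_, ho, wo, _, _ = win.shape
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * k * k)
    wmat = weight.data.reshape(cout, cin * k * k)
    out = (col @ wmat.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        gw = (gmat.T @ col).reshape(weight.shape)
        gcol = (gmat @ wmat).reshape(n, ho, wo, cin, k, k)
        gx = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                di, dj = ki * dilation, kj * dilation
                gx[:, :, di:di + ho * stride:stride, dj:dj + wo * stride:stride] += \
                    gcol[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        if bias is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, backward)


def _conv2d_depthwise(x: Tensor, weight: Tensor, bias: Tensor | None,
                      stride: int, padding: int, dilation: int) -> Tensor:
    c = x.shape[1]
    k = weight.shape[2]
    keff = (k - 1) * dilation + 1
    xp = _pad_input(x.data, padding)
    win = sliding_window_view(xp, (keff, keff), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # N,C,Ho,Wo,k,k
    n, _, ho, wo, _, _ = win.shape
    wk = weight.data.reshape(c, k, k)
    out = np.einsum("nchwij,cij->nchw", win, wk, optimize=True)
    if bias is not None:
        out = out + bias.data.reshape(1, c, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gw = np.einsum("nchwij,nchw->cij", win, g, optimize=True).reshape(weight.shape)
        gx = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                di, dj = ki * dilation, kj * dilation
                gx[:, :, di:di + ho * stride:stride, dj:dj + wo * stride:stride] += \
                    g * wk[:, ki, kj].reshape(1, c, 1, 1)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        if bias is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    """Max pooling; padded positions are -inf so they never win."""
    x = as_tensor(x)
    stride = stride or kernel
    xp = _pad_input(x.data, padding, value=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo, _, _ = win.shape
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = np.ascontiguousarray(out)

    def backward(g):
        gx = np.zeros_like(xp)
        ki, kj = np.divmod(arg, kernel)
        ii = np.arange(ho)[None, None, :, None] * stride + ki
        jj = np.arange(wo)[None, None, None, :] * stride + kj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(gx, (nn, cc, ii, jj), g)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        return (gx,)

    return Tensor._make(out, (x,), backward)


def upsample_nearest(x: Tensor, scale: int = 2) -> Tensor:
    x = as_tensor(x)
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        n, c, h, w = x.shape
        return (g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)),)

    return Tensor._make(out, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray, *,
                 training: bool, momentum: float = 0.03,
                 eps: float = 1e-3) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays updated in place when
    ``training`` is true (gradients never flow through them).
    """
    x = as_tensor(x)
    c = x.shape[1]
    if training:
        axes = (0, 2, 3)
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        running_mean += momentum * (m - running_mean)
        # biased variance, so stats recomputed over a full pass reproduce
        # training-mode normalisation exactly
        running_var += momentum * (v - running_var)
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)
    out = out.astype(x.dtype, copy=False)

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gs = g * gamma.data.reshape(1, c, 1, 1)
        if not training:
            return (gs * inv.reshape(1, c, 1, 1), ggamma, gbeta)
        nelem = x.data.size // c
        gxhat_mean = gs.mean(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        gxhat_xhat_mean = (gs * xhat).mean(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        gx = (gs - gxhat_mean - xhat * gxhat_xhat_mean) * inv.reshape(1, c, 1, 1)
        return (gx, ggamma, gbeta)

    return Tensor._make(out, (x, gamma, beta), backward)


def binary_cross_entropy_with_logits(logits: Tensor, target: Tensor | np.ndarray,
                                     reduction: str = "mean") -> Tensor:
    """Numerically stable BCE on logits: max(z,0) - z*t + log(1+exp(-|z|))."""
    logits = as_tensor(logits)
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    z = logits.data
    loss_data = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-z))

    def backward(g):
        return (g * (sig - t),)

    out = Tensor._make(loss_data, (logits,), backward)
    if reduction == "mean":
        return out.mean()
    if reduction == "sum":
        return out.sum()
    return out
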