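"""Spatial primitives (convolution, pooling, resizing) on :class:`Tensor`.

Convolution is im2col + BLAS matmul; its backward pass re-scatters the column
gradient with (k x k) strided slice additions, which also covers dilation and
stride exactly.  Resizing is expressed as two dense separable interpolation
matrices, so its adjoint is simply the transposed matrices.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "max_pool2d", "resize2d", "bce_with_logits"]


def _out_size(size: int, k: int, stride: int, pad: int, dil: int) -> int:
    ke = (k - 1) * dil + 1
    return (size + 2 * pad - ke) // stride + 1


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernels."""
    B, Cin, H, W = x.shape
    Cout, Cin_w, kh, kw = weight.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d: input has {Cin} channels, weight expects {Cin_w}")
    Ho = _out_size(H, kh, stride, padding, dilation)
    Wo = _out_size(W, kw, stride, padding, dilation)
    if Ho <= 0 or Wo <= 0:
        raise ValueError(f"conv2d: output would be empty for input {H}x{W}, kernel {kh}")

    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh * dilation - dilation + 1,) * 2, axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # B,Cin,Ho,Wo,kh,kw
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, Cin * kh * kw
    )
    wmat = weight.data.reshape(Cout, -1)
    out = (col @ wmat.T).reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Cout)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            weight._accum((gmat.T @ col).reshape(weight.shape))
        if x.requires_grad:
            dcol = (gmat @ wmat).reshape(B, Ho, Wo, Cin, kh, kw).transpose(3, 4, 5, 0, 1, 2)
            Hp, Wp = H + 2 * padding, W + 2 * padding
            dxp = np.zeros((B, Cin, Hp, Wp), dtype=np.float32)
            for ki in range(kh):
                hs = ki * dilation
                for kj in range(kw):
                    ws = kj * dilation
                    dxp[
                        :, :, hs : hs + Ho * stride : stride, ws : ws + Wo * stride : stride
                    ] += dcol[:, ki, kj].transpose(1, 0, 2, 3)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out.astype(np.float32, copy=False), parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    B, C, H, W = x.shape
    Ho = _out_size(H, kernel, stride, padding, 1)
    Wo = _out_size(W, kernel, stride, padding, 1)
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                    constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        Hp, Wp = H + 2 * padding, W + 2 * padding
        dxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
        ho, wo = np.meshgrid(np.arange(Ho), np.arange(Wo), indexing="ij")
        hh = ho[None, None] * stride + arg // kernel
        ww = wo[None, None] * stride + arg % kernel
        bb = np.arange(B)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        np.add.at(dxp, (bb, cc, hh, ww), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    return Tensor._make(out.astype(np.float32, copy=False), (x,), backward)


def _interp_matrix(n_in: int, n_out: int, mode: str) -> np.ndarray:
    """Dense (n_out, n_in) interpolation operator, half-pixel convention."""
    R = np.zeros((n_out, n_in), dtype=np.float32)
    if mode == "nearest":
        src = np.minimum((np.arange(n_out) * n_in) // n_out, n_in - 1)
        R[np.arange(n_out), src] = 1.0
    elif mode == "bilinear":
        src = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        t = (src - i0).astype(np.float32)
        R[np.arange(n_out), i0] += 1.0 - t
        R[np.arange(n_out), i1] += t
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return R


def resize2d(x: Tensor, scale: int, mode: str = "bilinear") -> Tensor:
    """Upsample the two trailing spatial dims by an integer factor."""
    B, C, H, W = x.shape
    Rh = _interp_matrix(H, H * scale, mode)
    Rw = _interp_matrix(W, W * scale, mode)
    out = np.matmul(Rh, np.matmul(x.data, Rw.T))

    def backward(g):
        if x.requires_grad:
            x._accum(np.matmul(Rh.T, np.matmul(g, Rw)))

    return Tensor._make(out.astype(np.float32, copy=False), (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed in logit space (never forms log p).

    Uses max(z,0) - z*y + log(1 + exp(-|z|)), whose gradient is
    (sigmoid(z) - y) / N.
    """
    y = np.asarray(targets, dtype=np.float32)
    if y.shape != logits.shape:
        raise ValueError(f"bce_with_logits: shape mismatch {y.shape} vs {logits.shape}")
    z = logits.data
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        if logits.requires_grad:
            p = np.empty_like(z)
            pos = z >= 0
            p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
            ez = np.exp(z[~pos])
            p[~pos] = ez / (1.0 + ez)
            logits._accum(g * (p - y) / n)

    return Tensor._make(np.float32(loss.mean()), (logits,), backward)
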