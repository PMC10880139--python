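"""im2col-based 2D/3D convolution primitives for the tensor engine."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _make, astensor

__all__ = ["conv2d", "conv3d"]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of ``x`` (B, Cin, H, W) with ``w`` (Cout, Cin, kh, kw)."""
    x, w, b = astensor(x), astensor(w), astensor(b)
    B, Cin, H, W = x.data.shape
    Cout, Cin_w, kh, kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    if Hp < kh or Wp < kw:
        raise ValueError(f"input {x.data.shape} too small for kernel ({kh},{kw})")
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (B, Cin, Ho, Wo, kh, kw) -> (B, Ho, Wo, Cin*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, Ho, Wo, -1)
    wmat = w.data.reshape(Cout, -1)
    out = cols @ wmat.T + b.data  # (B, Ho, Wo, Cout)
    out = out.transpose(0, 3, 1, 2)

    def bw(g):
        gt = g.transpose(0, 2, 3, 1)  # (B, Ho, Wo, Cout)
        b._accum(gt.sum(axis=(0, 1, 2)))
        gw = np.tensordot(gt, cols, axes=([0, 1, 2], [0, 1, 2]))
        w._accum(gw.reshape(w.data.shape))
        dcols = (gt @ wmat).reshape(B, Ho, Wo, Cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, Cin, Hp, Wp))
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[..., i, j]
        x._accum(dxp[:, :, p : Hp - p, p : Wp - p] if p else dxp)

    return _make(out, (x, w, b), bw)


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of ``x`` (B, Cin, D, H, W) with ``w`` (Cout, Cin, kd, kh, kw)."""
    x, w, b = astensor(x), astensor(w), astensor(b)
    B, Cin, D, H, W = x.data.shape
    Cout, Cin_w, kd, kh, kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    s, p = int(stride), int(padding)
    pad = ((0, 0), (0, 0), (p, p), (p, p), (p, p))
    xp = np.pad(x.data, pad) if p else x.data
    Dp, Hp, Wp = xp.shape[2:]
    if Dp < kd or Hp < kh or Wp < kw:
        raise ValueError(f"input {x.data.shape} too small for kernel ({kd},{kh},{kw})")
    Do = (Dp - kd) // s + 1
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    # (B, Cin, Do, Ho, Wo, kd, kh, kw) -> (B, Do, Ho, Wo, Cin*kd*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        B, Do, Ho, Wo, -1
    )
    wmat = w.data.reshape(Cout, -1)
    out = (cols @ wmat.T + b.data).transpose(0, 4, 1, 2, 3)

    def bw(g):
        gt = g.transpose(0, 2, 3, 4, 1)  # (B, Do, Ho, Wo, Cout)
        b._accum(gt.sum(axis=(0, 1, 2, 3)))
        gw = np.tensordot(gt, cols, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        w._accum(gw.reshape(w.data.shape))
        dcols = (gt @ wmat).reshape(B, Do, Ho, Wo, Cin, kd, kh, kw)
        dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((B, Cin, Dp, Hp, Wp))
        for a in range(kd):
            for i in range(kh):
                for j in range(kw):
                    dxp[
                        :,
                        :,
                        a : a + s * Do : s,
                        i : i + s * Ho : s,
                        j : j + s * Wo : s,
                    ] += dcols[..., a, i, j]
        x._accum(dxp[:, :, p : Dp - p, p : Hp - p, p : Wp - p] if p else dxp)

    return _make(out, (x, w, b), bw)
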