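"""Structured differentiable operations: convolution and upsampling.

conv2d uses an im2col forward (numpy sliding windows + one matmul) and a
slice-accumulate col2im backward, which keeps desk-scale training fast on
a single CPU.  Bilinear upsampling is expressed as two fixed interpolation
matrices so its adjoint is exact.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "upsample2x"]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input.

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    """
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (xp.shape[2] - kh) // s + 1
    wo = (xp.shape[3] - kw) // s + 1
    # (N, Cin, Ho, Wo, kh, kw) view, no copy
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T                       # (N, Ho*Wo, Cout)
    out = out.transpose(0, 2, 1).reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    cols_cache = cols  # retained for the weight gradient

    def bw(g):
        gmat = g.reshape(n, cout, ho * wo).transpose(0, 2, 1)  # (N,HoWo,Cout)
        gw = np.einsum("npc,npk->ck", gmat, cols_cache).reshape(w.data.shape)
        gcols = gmat @ wmat                                    # (N,HoWo,CinKhKw)
        gcols = gcols.reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[:, :, :, :, i, j]
        gx = gxp[:, :, p:p + h, p:p + wd] if p else gxp
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._make(out, parents, bw)


@lru_cache(maxsize=32)
def _interp_matrix(n: int) -> np.ndarray:
    """(2n, n) bilinear 2x interpolation matrix, half-pixel-centre convention."""
    m = np.zeros((2 * n, n), dtype=np.float32)
    for i in range(2 * n):
        # source coordinate of output sample i (align_corners=False)
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    return m


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling of an NCHW tensor."""
    n, c, h, w = x.data.shape
    mr = _interp_matrix(h)
    mc = _interp_matrix(w)
    out = np.einsum("ij,ncjk,lk->ncil", mr, x.data, mc, optimize=True)

    def bw(g):
        return (np.einsum("ij,ncil,lk->ncjk", mr, g, mc, optimize=True),)

    return Tensor._make(out, (x,), bw)
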