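"""Numba-compiled inner loops for the pooling layers.

Max-pooling (ceiling division, stride = kernel) and its backward pass are
memory-bound; fusing window max, tie counting and gradient routing into
single passes keeps a training step fast on one CPU core.  Everything here
is an internal detail of :mod:`lite3d.net`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True)
def pool_max_forward(xp: np.ndarray, kd: int, kh: int, kw: int) -> np.ndarray:
    """Window max over a -inf padded (B,C,Dp,Hp,Wp) tensor."""
    b, c, dp, hp, wp = xp.shape
    do, ho, wo = dp // kd, hp // kh, wp // kw
    out = np.empty((b, c, do, ho, wo), dtype=np.float32)
    for bi in range(b):
        for ci in range(c):
            for zi in range(do):
                for yi in range(ho):
                    for xi in range(wo):
                        m = np.float32(-np.inf)
                        for p in range(kd):
                            for q in range(kh):
                                for r in range(kw):
                                    v = xp[bi, ci, zi * kd + p,
                                           yi * kh + q, xi * kw + r]
                                    if v > m:
                                        m = v
                        out[bi, ci, zi, yi, xi] = m
    return out


@njit(fastmath=True)
def pool_max_backward(
    xp: np.ndarray,
    out: np.ndarray,
    gout: np.ndarray,
    kd: int,
    kh: int,
    kw: int,
    d: int,
    h: int,
    w: int,
) -> np.ndarray:
    """Route gradients to max positions, splitting equally among ties."""
    b, c, do, ho, wo = out.shape
    gin = np.zeros((b, c, d, h, w), dtype=np.float32)
    for bi in range(b):
        for ci in range(c):
            for zi in range(do):
                for yi in range(ho):
                    for xi in range(wo):
                        m = out[bi, ci, zi, yi, xi]
                        ties = 0
                        for p in range(kd):
                            for q in range(kh):
                                for r in range(kw):
                                    if xp[bi, ci, zi * kd + p, yi * kh + q,
                                          xi * kw + r] == m:
                                        ties += 1
                        g = gout[bi, ci, zi, yi, xi] / ties
                        for p in range(kd):
                            for q in range(kh):
                                for r in range(kw):
                                    zz = zi * kd + p
                                    yy = yi * kh + q
                                    xx = xi * kw + r
                                    if zz < d and yy < h and xx < w:
                                        if xp[bi, ci, zz, yy, xx] == m:
                                            gin[bi, ci, zz, yy, xx] = g
    return gin
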