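"""Compiled inner loops for the pruning engine (numba).

All arrays are float64 and C-contiguous: P is (ncat, 4, 4), partials are
(ncat, npat, 4), scalers are (ncat, npat), tips are (npat, 4).
"""

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=True, fastmath=True)
def msg_into(out, P, below, multiply):
    """out[c,p,i] (*)= sum_j P[c,i,j] * below[c,p,j]."""
    C, Np, _ = below.shape
    for c in range(C):
        for p in range(Np):
            b0 = below[c, p, 0]; b1 = below[c, p, 1]
            b2 = below[c, p, 2]; b3 = below[c, p, 3]
            for i in range(4):
                s = (P[c, i, 0] * b0 + P[c, i, 1] * b1
                     + P[c, i, 2] * b2 + P[c, i, 3] * b3)
                if multiply:
                    out[c, p, i] *= s
                else:
                    out[c, p, i] = s


@njit(cache=True, fastmath=True)
def msg_tip_into(out, P, tip, multiply):
    """Leaf variant: tip is (npat, 4), shared across categories."""
    C = P.shape[0]
    Np = tip.shape[0]
    for c in range(C):
        for p in range(Np):
            b0 = tip[p, 0]; b1 = tip[p, 1]; b2 = tip[p, 2]; b3 = tip[p, 3]
            for i in range(4):
                s = (P[c, i, 0] * b0 + P[c, i, 1] * b1
                     + P[c, i, 2] * b2 + P[c, i, 3] * b3)
                if multiply:
                    out[c, p, i] *= s
                else:
                    out[c, p, i] = s


@njit(cache=True, fastmath=True)
def msg_transposed_into(out, P, outer):
    """out[c,p,j] = sum_i outer[c,p,i] * P[c,i,j] (parent-side propagation)."""
    C, Np, _ = outer.shape
    for c in range(C):
        for p in range(Np):
            o0 = outer[c, p, 0]; o1 = outer[c, p, 1]
            o2 = outer[c, p, 2]; o3 = outer[c, p, 3]
            for j in range(4):
                out[c, p, j] = (o0 * P[c, 0, j] + o1 * P[c, 1, j]
                                + o2 * P[c, 2, j] + o3 * P[c, 3, j])


@njit(cache=True, fastmath=True)
def rescale(arr, scale):
    """Divide by the per-(cat,pattern) max and add its log to the scaler."""
    C, Np, _ = arr.shape
    for c in range(C):
        for p in range(Np):
            m = arr[c, p, 0]
            for i in range(1, 4):
                if arr[c, p, i] > m:
                    m = arr[c, p, i]
            if m <= _TINY:
                m = _TINY
            inv = 1.0 / m
            for i in range(4):
                arr[c, p, i] *= inv
            scale[c, p] += np.log(m)


@njit(cache=True, fastmath=True)
def edge_ll(P, outer, below, wmix, weights):
    """Total ln L for one edge: mixture weights wmix prefolded with scalers."""
    C, Np, _ = outer.shape
    tot = 0.0
    for p in range(Np):
        acc = 0.0
        for c in range(C):
            v = 0.0
            b0 = below[c, p, 0]; b1 = below[c, p, 1]
            b2 = below[c, p, 2]; b3 = below[c, p, 3]
            for i in range(4):
                s = (P[c, i, 0] * b0 + P[c, i, 1] * b1
                     + P[c, i, 2] * b2 + P[c, i, 3] * b3)
                v += outer[c, p, i] * s
            acc += wmix[c, p] * v
        if acc < _TINY:
            acc = _TINY
        tot += weights[p] * np.log(acc)
    return tot


@njit(cache=True, fastmath=True)
def edge_ll_tip(P, outer, tip, wmix, weights):
    C, Np, _ = outer.shape
    tot = 0.0
    for p in range(Np):
        acc = 0.0
        b0 = tip[p, 0]; b1 = tip[p, 1]; b2 = tip[p, 2]; b3 = tip[p, 3]
        for c in range(C):
            v = 0.0
            for i in range(4):
                s = (P[c, i, 0] * b0 + P[c, i, 1] * b1
                     + P[c, i, 2] * b2 + P[c, i, 3] * b3)
                v += outer[c, p, i] * s
            acc += wmix[c, p] * v
        if acc < _TINY:
            acc = _TINY
        tot += weights[p] * np.log(acc)
    return tot
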