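"""Numba kernels for genome-scale partition-function evaluation.

``pf_matrix`` evaluates the duplex partition function for every pair of
l-nt segments of two sequence regions, using the same helix/loop grammar
and energy terms as :func:`mtmisalign.thermo.duplex_partition_function`
(linear-space accumulation; exact in float64 for the <= 100-nt grid).

Inputs are uint8 base codes.  ``zb`` must already be in the stacked
orientation: for an H-strand region this is the base-wise complement of the
reference slice in reference coordinate order, so that segment pair (a, b)
corresponds to reference segments starting at the mapped positions and a
Watson-Crick pair means identical reference bases (the direct-repeat
picture of misalignment).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# pair-type codes, kept in sync with mtmisalign.thermo.params
_PAIR_NONE, _PAIR_WC, _PAIR_MM = 0, 1, 2


@njit(cache=True, fastmath=True)
def pf_matrix(xa, zb, l, wstep, pairt, loopw, maxloop, wat, initw):  # pragma: no cover
    """Partition function of every l x l segment pair of two regions.

    Returns D of shape (len(xa)-l+1, len(zb)-l+1) with
    D[a, b] = Z(xa[a:a+l], zb[b:b+l]).
    """
    nA = xa.size - l + 1
    nB = zb.size - l + 1
    D = np.zeros((nA, nB))
    H1 = np.zeros((l, l))
    Hx = np.zeros((l, l))
    Hm = np.zeros((l, l))
    for a in range(nA):
        for b in range(nB):
            total = 0.0
            for i in range(l):
                xi = xa[a + i]
                for k in range(l):
                    zk = zb[b + k]
                    t = pairt[xi, zk]
                    h1 = 0.0
                    hx = 0.0
                    hm = 0.0
                    if t == _PAIR_WC:
                        term = wat[xi]
                        s = term
                        for li in range(maxloop + 1):
                            ii = i - 1 - li
                            if ii < 0:
                                break
                            for lj in range(maxloop - li + 1):
                                kk = k - 1 - lj
                                if kk < 0:
                                    break
                                sz = li + lj
                                if sz >= 1:
                                    s += Hx[ii, kk] * loopw[sz]
                        h1 = s
                        if i > 0 and k > 0:
                            w = wstep[xa[a + i - 1], xi, zb[b + k - 1], zk]
                            hx = (
                                H1[i - 1, k - 1]
                                + Hx[i - 1, k - 1]
                                + Hm[i - 1, k - 1]
                            ) * w
                        total += hx * term
                    elif t == _PAIR_MM:
                        if i > 0 and k > 0:
                            w = wstep[xa[a + i - 1], xi, zb[b + k - 1], zk]
                            hm = (H1[i - 1, k - 1] + Hx[i - 1, k - 1]) * w
                    H1[i, k] = h1
                    Hx[i, k] = hx
                    Hm[i, k] = hm
            D[a, b] = total * initw
    return D


@njit(cache=True)
def box_sums(sat, i0, j0, h, w):  # pragma: no cover
    """Rectangle sums from a summed-area table for vectors of corners."""
    n = i0.size
    out = np.empty((n,), dtype=np.float64)
    for t in range(n):
        a = i0[t]
        b = j0[t]
        out[t] = (
            sat[a + h, b + w] - sat[a, b + w] - sat[a + h, b] + sat[a, b]
        )
    return out
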