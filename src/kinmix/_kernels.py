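"""Compiled forward-pass kernel.

Same arithmetic as the recursive divide-and-conquer step in ``hmm.py`` but
iterative (one in-place 2x2 sweep per bit, top bit first), which is what the
recursion unrolls to.  Falls back to pure Python if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _apply_bit(v, stride, t00, t01, t10, t11):
    N = v.shape[0]
    base = 0
    while base < N:
        for t in range(stride):
            x0 = v[base + t]
            x1 = v[base + stride + t]
            v[base + t] = t00 * x0 + t10 * x1
            v[base + stride + t] = t01 * x0 + t11 * x1
        base += 2 * stride
    return v


@njit(cache=True)
def forward_loglik_chrom(h1, h2, freqA, freqB, gap, rec,
                         rateAB, rateBA, pp, cap, pop1, pop2, init):
    """Scaled forward pass over one chromosome; returns its log-likelihood."""
    N = init.shape[0]
    n = h1.shape[0]
    nf = rateAB.shape[0]
    b = 0
    while (1 << b) < N:
        b += 1

    v = np.empty(N, dtype=np.float64)
    # site 0: initial distribution times emissions
    ll = 0.0
    s = 0.0
    for st in range(N):
        fa = freqB[0] if pop1[st] == 1 else freqA[0]
        e1 = fa if h1[0] == 1 else 1.0 - fa
        fb = freqB[0] if pop2[st] == 1 else freqA[0]
        e2 = fb if h2[0] == 1 else 1.0 - fb
        v[st] = init[st] * e1 * e2
        s += v[st]
    if s <= 0.0:
        return -np.inf
    inv = 1.0 / s
    for st in range(N):
        v[st] *= inv
    ll += np.log(s)

    for i in range(1, n):
        d = gap[i]
        r = rec[i]
        # phase bit (packed MSB-first: bit 0 has stride N/2)
        sp = d * pp
        if sp > cap:
            sp = cap
        _apply_bit(v, N >> 1, 1.0 - sp, sp, sp, 1.0 - sp)
        # founder-ancestry bits
        for j in range(nf):
            sab = d * rateAB[j]
            if sab > cap:
                sab = cap
            sba = d * rateBA[j]
            if sba > cap:
                sba = cap
            _apply_bit(v, N >> (2 + j), 1.0 - sab, sab, sba, 1.0 - sba)
        # recombination bits
        for k in range(nf - 2):
            _apply_bit(v, N >> (2 + nf + k), 1.0 - r, r, r, 1.0 - r)
        # emissions and rescale
        s = 0.0
        for st in range(N):
            fa = freqB[i] if pop1[st] == 1 else freqA[i]
            e1 = fa if h1[i] == 1 else 1.0 - fa
            fb = freqB[i] if pop2[st] == 1 else freqA[i]
            e2 = fb if h2[i] == 1 else 1.0 - fb
            v[st] *= e1 * e2
            s += v[st]
        if s <= 0.0:
            return -np.inf
        inv = 1.0 / s
        for st in range(N):
            v[st] *= inv
        ll += np.log(s)
    return ll
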