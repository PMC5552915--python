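"""Log-space dynamic-programming kernels for profile-HMM scoring.

Everything here works on log2-odds emission matrices precomputed per
sequence (match and insert emission log-odds against the background) and
log2 transition vectors, so a single kernel serves forward (log-sum) and
Viterbi (max) scoring in both alignment modes:

``local``
    A hit is a path entering the core at any match state (uniform entry
    probability 1/L), moving through match/insert/delete states with the
    profile's transitions, and exiting from any match state; sequence
    residues outside the hit are flanking and scored by the background,
    contributing zero log-odds.
``global``
    The classic begin-to-end recursion over the whole sequence using the
    full node-0..L topology including the terminal inserts I_0 and I_L.

All arithmetic is log2.  Sums of path probabilities use an exact
max-plus-sum-of-exponentials accumulation; terms more than 45 bits below
the maximum are dropped, which perturbs the result by well under 1e-9
bits per cell.  Kernels are numba-compiled (cached) because the
screening stage scores every CDS against every family profile.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf

_LN2 = math.log(2.0)
_INV_LN2 = 1.0 / _LN2
_CUTOFF = -45.0  # bits below the max at which a summand is negligible


@njit(cache=True, inline="always")
def _lse2(a: float, b: float) -> float:
    """log2(2**a + 2**b), safe for -inf."""
    if a < b:
        a, b = b, a
    if b == -math.inf:  # also covers a == b == -inf (avoid inf - inf)
        return a
    d = b - a
    if d < _CUTOFF:
        return a
    return a + math.log1p(math.exp(d * _LN2)) * _INV_LN2


@njit(cache=True, inline="always")
def _lse4(a: float, b: float, c: float, d: float) -> float:
    """log2 of the sum of four 2**x terms via one max and one log."""
    m = a
    if b > m:
        m = b
    if c > m:
        m = c
    if d > m:
        m = d
    if m == -math.inf:
        return m
    s = 0.0
    if a - m >= _CUTOFF:
        s += math.exp((a - m) * _LN2)
    if b - m >= _CUTOFF:
        s += math.exp((b - m) * _LN2)
    if c - m >= _CUTOFF:
        s += math.exp((c - m) * _LN2)
    if d - m >= _CUTOFF:
        s += math.exp((d - m) * _LN2)
    return m + math.log(s) * _INV_LN2


@njit(cache=True)
def dp_local(lom, lins, tmm, tmi, tmd, tim, tii, tdm, tdd, viterbi):
    """Local (free-flank) log2-odds score.

    lom : (n, L) match log-odds per (position, state)
    lins: (n, L + 1) insert log-odds per (position, node)
    t** : (L + 1,) log2 transition probabilities
    """
    n, L = lom.shape
    entry = -math.log2(L)
    M = np.full((n + 1, L + 1), NEG_INF)
    I = np.full((n + 1, L + 1), NEG_INF)
    D = np.full((n + 1, L + 1), NEG_INF)
    total = NEG_INF
    for i in range(1, n + 1):
        for k in range(1, L + 1):
            a = entry  # start a fresh hit at M_k
            if k > 1:
                b = M[i - 1, k - 1] + tmm[k - 1]
                c = I[i - 1, k - 1] + tim[k - 1]
                d = D[i - 1, k - 1] + tdm[k - 1]
                if viterbi:
                    if b > a:
                        a = b
                    if c > a:
                        a = c
                    if d > a:
                        a = d
                    v = a
                else:
                    v = _lse4(a, b, c, d)
            else:
                v = a
            M[i, k] = lom[i - 1, k - 1] + v
            if k < L:
                a = M[i - 1, k] + tmi[k]
                b = I[i - 1, k] + tii[k]
                I[i, k] = lins[i - 1, k] + (max(a, b) if viterbi else _lse2(a, b))
            if k > 1:
                a = M[i, k - 1] + tmd[k - 1]
                b = D[i, k - 1] + tdd[k - 1]
                D[i, k] = max(a, b) if viterbi else _lse2(a, b)
            # exit from any match state, flanks free
            if viterbi:
                if M[i, k] > total:
                    total = M[i, k]
            else:
                total = _lse2(total, M[i, k])
    return total


@njit(cache=True)
def dp_global(lom, lins, tmm, tmi, tmd, tim, tii, tdm, tdd, viterbi):
    """Global begin-to-end log2-odds score over the whole sequence."""
    n, L = lom.shape
    M = np.full((n + 1, L + 1), NEG_INF)
    I = np.full((n + 1, L + 1), NEG_INF)
    D = np.full((n + 1, L + 1), NEG_INF)
    M[0, 0] = 0.0  # Begin
    for k in range(1, L + 1):
        D[0, k] = M[0, 0] + tmd[0] if k == 1 else D[0, k - 1] + tdd[k - 1]
    for i in range(1, n + 1):
        for k in range(0, L + 1):
            if k > 0:
                a = M[i - 1, k - 1] + tmm[k - 1]
                b = I[i - 1, k - 1] + tim[k - 1]
                c = D[i - 1, k - 1] + tdm[k - 1]
                if viterbi:
                    v = max(a, max(b, c))
                else:
                    v = _lse2(a, _lse2(b, c))
                M[i, k] = lom[i - 1, k - 1] + v
            a = M[i - 1, k] + tmi[k]
            b = I[i - 1, k] + tii[k]
            v = max(a, b) if viterbi else _lse2(a, b)
            I[i, k] = lins[i - 1, k] + v
            if k > 0:
                a = M[i, k - 1] + tmd[k - 1]
                b = D[i, k - 1] + tdd[k - 1] if k > 1 else NEG_INF
                D[i, k] = max(a, b) if viterbi else _lse2(a, b)
    a = M[n, L] + tmm[L]
    b = I[n, L] + tim[L]
    c = D[n, L] + tdm[L]
    if viterbi:
        return max(a, max(b, c))
    return _lse2(a, _lse2(b, c))


def warmup() -> None:
    """Trigger JIT compilation of both kernels on a tiny problem."""
    lom = np.zeros((1, 1))
    lins = np.zeros((1, 2))
    t = np.zeros(2)
    for vit in (True, False):
        dp_local(lom, lins, t, t, t, t, t, t, t, vit)
        dp_global(lom, lins, t, t, t, t, t, t, t, vit)
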