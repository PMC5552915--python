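"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package's DP engine: scores
are computed by explicit enumeration of every state path in probability
space, pairwise alignment by a hand-written Gotoh DP, and the t-tail
probability by the classic continued-fraction incomplete beta.
"""

from __future__ import annotations

import math

from phoscan.io import AMINO_ACIDS
from phoscan.profiles import ProfileHMM


def _odds(profile: ProfileHMM, seq: str):
    """Per-position emission odds (match and insert) in probability space."""
    aa = {c: i for i, c in enumerate(AMINO_ACIDS)}
    m = []
    ins = []
    for ch in seq:
        if ch == "X":
            m.append([1.0] * (profile.L + 1))
            ins.append([1.0] * (profile.L + 1))
        else:
            r = aa[ch]
            q = profile.background[r]
            m.append([0.0] + [profile.match_emissions[k, r] / q
                              for k in range(profile.L)])
            ins.append([profile.insert_emissions[k, r] / q
                        for k in range(profile.L + 1)])
    return m, ins


def enumerate_local(profile: ProfileHMM, seq: str) -> tuple[float, float]:
    """(forward_bits, viterbi_bits) by explicit path enumeration, local mode.

    A path enters at any match state (probability 1/L), walks the core
    with the profile transitions (inserts only between matches, deletes
    reachable from node 2 on), and may exit freely after any match.
    Flanking residues are background-scored (odds 1).
    """
    L, n = profile.L, len(seq)
    m, ins = _odds(profile, seq)
    tmm, tmi, tmd = profile.t_mm, profile.t_mi, profile.t_md
    tim, tii = profile.t_im, profile.t_ii
    tdm, tdd = profile.t_dm, profile.t_dd
    total = 0.0

    def walk(kind: str, k: int, pos: int, w: float) -> None:
        # pos = index of last emitted residue
        nonlocal total
        if kind == "M":
            total += w
            if k < L and pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tmm[k] * m[pos + 1][k + 1])
            if 1 <= k <= L - 1 and pos + 1 < n:
                walk("I", k, pos + 1, w * tmi[k] * ins[pos + 1][k])
            if k < L:
                walk("D", k + 1, pos, w * tmd[k])
        elif kind == "I":
            if pos + 1 < n:
                walk("I", k, pos + 1, w * tii[k] * ins[pos + 1][k])
            if k < L and pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tim[k] * m[pos + 1][k + 1])
        else:  # D
            if k < L and pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tdm[k] * m[pos + 1][k + 1])
            if k < L:
                walk("D", k + 1, pos, w * tdd[k])

    for s in range(n):
        for k in range(1, L + 1):
            walk("M", k, s, (1.0 / L) * m[s][k])
    return math.log2(total), math.log2(_best_local(profile, seq))


def _best_local(profile: ProfileHMM, seq: str) -> float:
    """Max path weight, recomputed cleanly (enumeration with max)."""
    L, n = profile.L, len(seq)
    m, ins = _odds(profile, seq)
    tmm, tmi, tmd = profile.t_mm, profile.t_mi, profile.t_md
    tim, tii = profile.t_im, profile.t_ii
    tdm, tdd = profile.t_dm, profile.t_dd
    best = 0.0

    def walk(kind, k, pos, w):
        nonlocal best
        if kind == "M":
            best = max(best, w)
            if k < L and pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tmm[k] * m[pos + 1][k + 1])
            if 1 <= k <= L - 1 and pos + 1 < n:
                walk("I", k, pos + 1, w * tmi[k] * ins[pos + 1][k])
            if k < L:
                walk("D", k + 1, pos, w * tmd[k])
        elif kind == "I":
            if pos + 1 < n:
                walk("I", k, pos + 1, w * tii[k] * ins[pos + 1][k])
            if k < L and pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tim[k] * m[pos + 1][k + 1])
        else:
            if k < L and pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tdm[k] * m[pos + 1][k + 1])
            if k < L:
                walk("D", k + 1, pos, w * tdd[k])

    for s in range(n):
        for k in range(1, L + 1):
            walk("M", k, s, (1.0 / L) * m[s][k])
    return best


def enumerate_global(profile: ProfileHMM, seq: str) -> tuple[float, float]:
    """(forward_bits, viterbi_bits) by path enumeration, global mode."""
    L, n = profile.L, len(seq)
    m, ins = _odds(profile, seq)
    tmm, tmi, tmd = profile.t_mm, profile.t_mi, profile.t_md
    tim, tii = profile.t_im, profile.t_ii
    tdm, tdd = profile.t_dm, profile.t_dd
    total = 0.0
    best = 0.0

    def walk(kind, k, pos, w):
        # pos = index of last emitted residue (-1 before any emission)
        nonlocal total, best
        if kind == "M":
            if k == L:
                if pos == n - 1:
                    total += w * tmm[L]
                    best = max(best, w * tmm[L])
                if pos + 1 < n:
                    walk("I", L, pos + 1, w * tmi[L] * ins[pos + 1][L])
                return
            if pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tmm[k] * m[pos + 1][k + 1])
                walk("I", k, pos + 1, w * tmi[k] * ins[pos + 1][k])
            walk("D", k + 1, pos, w * tmd[k])
        elif kind == "I":
            if k == L:
                if pos == n - 1:
                    total += w * tim[L]
                    best = max(best, w * tim[L])
            elif pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tim[k] * m[pos + 1][k + 1])
            if pos + 1 < n:
                walk("I", k, pos + 1, w * tii[k] * ins[pos + 1][k])
        else:  # D_k
            if k == L:
                if pos == n - 1:
                    total += w * tdm[L]
                    best = max(best, w * tdm[L])
                return
            if pos + 1 < n:
                walk("M", k + 1, pos + 1, w * tdm[k] * m[pos + 1][k + 1])
            walk("D", k + 1, pos, w * tdd[k])

    walk("M", 0, -1, 1.0)  # node 0 = Begin
    return math.log2(total), math.log2(best)


# ---------------------------------------------------------------------------
# pairwise local alignment (Gotoh affine-gap Smith-Waterman)

def sw_score(query: str, ref: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Raw local alignment score; a gap of length g costs open + (g-1)*extend."""
    n, m = len(query), len(ref)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (query consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            s = matrix[query[i - 1], ref[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# t distribution tail, by continued-fraction incomplete beta

def _betacf(a: float, b: float, x: float) -> float:
    MAXIT, EPS, FPMIN = 200, 3e-14, 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < FPMIN:
        d = FPMIN
    d = 1.0 / d
    h = d
    for it in range(1, MAXIT + 1):
        m2 = 2 * it
        aa = it * (b - it) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < FPMIN:
            d = FPMIN
        c = 1.0 + aa / c
        if abs(c) < FPMIN:
            c = FPMIN
        d = 1.0 / d
        h *= d * c
        aa = -(a + it) * (qab + it) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < FPMIN:
            d = FPMIN
        c = 1.0 + aa / c
        if abs(c) < FPMIN:
            c = FPMIN
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < EPS:
            break
    return h


def _betai(a: float, b: float, x: float) -> float:
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_bt = (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log(1.0 - x)
    )
    bt = math.exp(ln_bt)
    if x < (a + 1.0) / (a + b + 2.0):
        return bt * _betacf(a, b, x) / a
    return 1.0 - bt * _betacf(b, a, 1.0 - x) / b


def t_two_tailed_p(t: float, df: float) -> float:
    """Two-tailed p-value of the t distribution."""
    return _betai(df / 2.0, 0.5, df / (df + t * t))
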