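"""Numba dynamic-programming kernels.

Two hot loops live here: the global affine-gap (Gotoh) alignment used for
percent identity, and the profile Viterbi recursion.  Both use a fixed,
fully specified tie-break so results are deterministic and reproducible by
an independent implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30

# State codes shared by the kernels and their callers.
ST_M, ST_D, ST_I = 0, 1, 2


@njit(cache=True)
def gotoh_align(a, b, sub, gap_open, gap_extend):
    """Global affine-gap alignment maximizing (score, identity count).

    ``a`` and ``b`` are integer-encoded sequences indexing into the square
    substitution matrix ``sub``.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``; end gaps are penalized.  The DP
    objective is lexicographic: maximize alignment score, then the number
    of identical aligned pairs; remaining ties resolve by preferring a
    diagonal step, then a gap in ``b`` (consume ``a``), then a gap in ``a``.

    Returns (score, aligned index pairs) where pairs is an (L, 2) int32
    array with -1 marking a gap.
    """
    n, m = len(a), len(b)
    # score / identity / pointer per state: 0 diag, 1 up (gap in b), 2 left
    S = np.full((3, n + 1, m + 1), NEG_INF)
    ID = np.zeros((3, n + 1, m + 1), dtype=np.int32)
    P = np.full((3, n + 1, m + 1), -2, dtype=np.int8)  # predecessor state

    S[0, 0, 0] = 0.0
    for i in range(1, n + 1):
        S[1, i, 0] = -gap_open - (i - 1) * gap_extend
        P[1, i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        S[2, 0, j] = -gap_open - (j - 1) * gap_extend
        P[2, 0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            # diagonal state: preference order M, up, left
            bs = NEG_INF
            bi = -1
            bp = -2
            for s in range(3):
                cs = S[s, i - 1, j - 1]
                ci = ID[s, i - 1, j - 1]
                if cs > bs or (cs == bs and ci > bi):
                    bs, bi, bp = cs, ci, s
            if bp >= 0:
                S[0, i, j] = bs + sub[ai, bj]
                ID[0, i, j] = bi + (1 if ai == bj else 0)
                P[0, i, j] = bp
            # up state (gap in b): open from M, extend from up
            os_ = S[0, i - 1, j] - gap_open
            oe = S[1, i - 1, j] - gap_extend
            oi = ID[0, i - 1, j]
            ei = ID[1, i - 1, j]
            if os_ > oe or (os_ == oe and oi >= ei):
                S[1, i, j] = os_
                ID[1, i, j] = oi
                P[1, i, j] = 0
            else:
                S[1, i, j] = oe
                ID[1, i, j] = ei
                P[1, i, j] = 1
            # left state (gap in a)
            os_ = S[0, i, j - 1] - gap_open
            oe = S[2, i, j - 1] - gap_extend
            oi = ID[0, i, j - 1]
            ei = ID[2, i, j - 1]
            if os_ > oe or (os_ == oe and oi >= ei):
                S[2, i, j] = os_
                ID[2, i, j] = oi
                P[2, i, j] = 0
            else:
                S[2, i, j] = oe
                ID[2, i, j] = ei
                P[2, i, j] = 2

    best_state = 0
    bs = S[0, n, m]
    bi = ID[0, n, m]
    for s in range(1, 3):
        if S[s, n, m] > bs or (S[s, n, m] == bs and ID[s, n, m] > bi):
            best_state = s
            bs = S[s, n, m]
            bi = ID[s, n, m]

    # traceback
    pairs = np.empty((n + m, 2), dtype=np.int32)
    k = 0
    i, j, s = n, m, best_state
    while i > 0 or j > 0:
        p = P[s, i, j]
        if s == 0:
            pairs[k, 0] = i - 1
            pairs[k, 1] = j - 1
            i -= 1
            j -= 1
        elif s == 1:
            pairs[k, 0] = i - 1
            pairs[k, 1] = -1
            i -= 1
        else:
            pairs[k, 0] = -1
            pairs[k, 1] = j - 1
            j -= 1
        k += 1
        s = p
    return bs, pairs[:k][::-1].copy()


@njit(cache=True)
def viterbi_profile(query, match_lo, tr, free_term):
    """Viterbi over a linear profile of match/insert/delete states.

    ``query``: integer-encoded residues (index into ``match_lo`` columns;
    -1 means background/ambiguous, log-odds 0).
    ``match_lo``: (k, n_alpha) per-match-state emission log-odds.
    ``tr``: transition log-probabilities
        [MM, MI, MD, II, IM, DD, DM].
    ``free_term``: when True, transitions touching the flanking insert
    states I_0 and I_k cost nothing (unaligned tails are free).

    Returns (score, path) where path is an (L, 2) int32 array of
    (state, profile column) with states 0=M, 1=D, 2=I; match/delete columns
    are 1-based, insert entries carry the preceding match column.
    """
    k = match_lo.shape[0]
    n = len(query)
    tMM, tMI, tMD, tII, tIM, tDD, tDM = tr

    M = np.full((n + 1, k + 1), NEG_INF)
    D = np.full((n + 1, k + 1), NEG_INF)
    I = np.full((n + 1, k + 1), NEG_INF)
    PM = np.full((n + 1, k + 1), -2, dtype=np.int8)
    PD = np.full((n + 1, k + 1), -2, dtype=np.int8)
    PI = np.full((n + 1, k + 1), -2, dtype=np.int8)

    M[0, 0] = 0.0  # begin state
    for j in range(1, k + 1):
        prev = M[0, j - 1] + tMD if j == 1 else D[0, j - 1] + tDD
        D[0, j] = prev
        PD[0, j] = ST_M if j == 1 else ST_D
    for i in range(1, n + 1):
        # I_0: free or penalized leading insert
        c_in = 0.0 if free_term else tMI
        c_self = 0.0 if free_term else tII
        fm = M[i - 1, 0] + c_in
        fi = I[i - 1, 0] + c_self
        if fm >= fi:
            I[i, 0] = fm
            PI[i, 0] = ST_M
        else:
            I[i, 0] = fi
            PI[i, 0] = ST_I

    for i in range(1, n + 1):
        ai = query[i - 1]
        for j in range(1, k + 1):
            emit = 0.0 if ai < 0 else match_lo[j - 1, ai]
            # M: predecessors in preference order M, D, I
            cm = M[i - 1, j - 1] + tMM
            cd = D[i - 1, j - 1] + tDM
            ji = j - 1  # insert state preceding column j
            c_out = 0.0 if (free_term and (ji == 0 or ji == k)) else tIM
            ci = I[i - 1, j - 1] + c_out
            best = cm
            ptr = ST_M
            if cd > best:
                best = cd
                ptr = ST_D
            if ci > best:
                best = ci
                ptr = ST_I
            M[i, j] = emit + best
            PM[i, j] = ptr
            # D: predecessors M, D (no I->D)
            cm = M[i, j - 1] + tMD
            cd = D[i, j - 1] + tDD
            if cm >= cd:
                D[i, j] = cm
                PD[i, j] = ST_M
            else:
                D[i, j] = cd
                PD[i, j] = ST_D
            # I_j: predecessors M, I (no D->I)
            c_in = 0.0 if (free_term and j == k) else tMI
            c_self = 0.0 if (free_term and j == k) else tII
            cm = M[i - 1, j] + c_in
            ci = I[i - 1, j] + c_self
            if cm >= ci:
                I[i, j] = cm
                PI[i, j] = ST_M
            else:
                I[i, j] = ci
                PI[i, j] = ST_I

    # end transitions: from M_k (tMM), D_k (tDM), I_k (free or tIM)
    c_end_i = 0.0 if free_term else tIM
    score = M[n, k] + tMM
    state = ST_M
    if D[n, k] + tDM > score:
        score = D[n, k] + tDM
        state = ST_D
    if I[n, k] + c_end_i > score:
        score = I[n, k] + c_end_i
        state = ST_I

    # traceback
    path = np.empty((n + k + 1, 2), dtype=np.int32)
    t = 0
    i, j, s = n, k, state
    while not (s == ST_M and i == 0 and j == 0):
        path[t, 0] = s
        path[t, 1] = j
        t += 1
        if s == ST_M:
            p = PM[i, j]
            i -= 1
            j -= 1
        elif s == ST_D:
            p = PD[i, j]
            j -= 1
        else:
            p = PI[i, j]
            i -= 1
        s = p
    return score, path[:t][::-1].copy()
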