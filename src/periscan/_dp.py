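"""Compiled dynamic-programming kernels.

All profile scoring reduces to a handful of dense DP recurrences; they are
compiled with numba because the all-vs-all scan over a whole proteome runs
millions of cells.  Everything here works on plain numpy arrays; the
object-level API lives in :mod:`periscan.profiles`.

Model layout (L match states, 0-based k):

* entry  B -> M_k      : ``entry[k]``
* match  M_k -> M_k+1  : ``tMM[k]``  (k < L-1)
*        M_k -> I_k    : ``tMI[k]``
*        M_k -> D_k+1  : ``tMD[k]``
*        M_k -> E      : ``texit[k]`` (local exit; 1.0 at k = L-1)
* insert I_k -> M_k+1  : ``tIM[k]``;  I_k -> I_k : ``tII[k]``
* delete D_k -> M_k+1  : ``tDM[k]``;  D_k -> D_k+1 : ``tDD[k]``

Alignments start and end on match states (Smith-Waterman-style locality);
unaligned flanking residues are emitted by the background and contribute
odds 1.  ``Eodds``/``iodds`` are emission-over-background odds ratios.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = 2.0**500
_SMALL = 2.0**-500


@njit(cache=True)
def forward_bits(x, Eodds, iodds, tMM, tMI, tMD, tIM, tII, tDM, tDD, entry, texit):
    """log2 of the summed path odds of a sequence against a profile.

    Sum over all start positions, entry/exit states and state paths of
    P(path) * prod(emission odds).  The caller applies the uniform start
    prior 1/(n+1).  Returns -inf for an empty sequence (every path must
    emit at least one match residue).
    """
    n = x.shape[0]
    L = Eodds.shape[0]
    if n == 0 or L == 0:
        return -np.inf

    fm = np.zeros(L)
    fi = np.zeros(L)
    fd = np.zeros(L)
    nm = np.zeros(L)
    ni = np.zeros(L)
    nd = np.zeros(L)

    acc = 0.0        # accumulated exit mass, in current scale units
    log_scale = 0.0  # log2 of the cumulative scaling applied
    inv_c = 1.0      # 1 / cumulative_scale, for fresh entry mass

    for i in range(n):
        xi = x[i]
        for k in range(L):
            prev = entry[k] * inv_c
            if k > 0:
                prev += fm[k - 1] * tMM[k - 1] + fi[k - 1] * tIM[k - 1] + fd[k - 1] * tDM[k - 1]
            nm[k] = Eodds[k, xi] * prev
            ni[k] = iodds[xi] * (fm[k] * tMI[k] + fi[k] * tII[k])
        nd[0] = 0.0
        for k in range(1, L):
            nd[k] = nm[k - 1] * tMD[k - 1] + nd[k - 1] * tDD[k - 1]
        for k in range(L):
            fm[k] = nm[k]
            fi[k] = ni[k]
            fd[k] = nd[k]
            acc += nm[k] * texit[k]

        peak = acc
        for k in range(L):
            if fm[k] > peak:
                peak = fm[k]
            if fi[k] > peak:
                peak = fi[k]
            if fd[k] > peak:
                peak = fd[k]
        if peak > _BIG or (0.0 < peak < _SMALL):
            for k in range(L):
                fm[k] /= peak
                fi[k] /= peak
                fd[k] /= peak
            acc /= peak
            inv_c /= peak
            log_scale += np.log2(peak)

    if acc <= 0.0:
        return -np.inf
    return np.log2(acc) + log_scale


@njit(cache=True)
def viterbi_best(x, lE, liodds, ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, lentry, ltexit):
    """Best single path in log2 space.

    Returns ``(score, start, end)``: the log2 odds of the best path and the
    0-based inclusive span of sequence residues it emits through match or
    insert states.
    """
    n = x.shape[0]
    L = lE.shape[0]
    NEG = -1e30
    if n == 0 or L == 0:
        return NEG, -1, -1

    vm = np.full(L, NEG)
    vi = np.full(L, NEG)
    vd = np.full(L, NEG)
    sm = np.zeros(L, dtype=np.int64)
    si = np.zeros(L, dtype=np.int64)
    sd = np.zeros(L, dtype=np.int64)
    nmv = np.full(L, NEG)
    niv = np.full(L, NEG)
    ndv = np.full(L, NEG)
    nms = np.zeros(L, dtype=np.int64)
    nis = np.zeros(L, dtype=np.int64)
    nds = np.zeros(L, dtype=np.int64)

    best = NEG
    best_s = -1
    best_e = -1

    for i in range(n):
        xi = x[i]
        for k in range(L):
            bv = lentry[k]
            bs = i
            if k > 0:
                c = vm[k - 1] + ltMM[k - 1]
                if c > bv:
                    bv, bs = c, sm[k - 1]
                c = vi[k - 1] + ltIM[k - 1]
                if c > bv:
                    bv, bs = c, si[k - 1]
                c = vd[k - 1] + ltDM[k - 1]
                if c > bv:
                    bv, bs = c, sd[k - 1]
            nmv[k] = lE[k, xi] + bv
            nms[k] = bs

            bv = vm[k] + ltMI[k]
            bs = sm[k]
            c = vi[k] + ltII[k]
            if c > bv:
                bv, bs = c, si[k]
            niv[k] = liodds[xi] + bv
            nis[k] = bs

        ndv[0] = NEG
        nds[0] = 0
        for k in range(1, L):
            bv = nmv[k - 1] + ltMD[k - 1]
            bs = nms[k - 1]
            c = ndv[k - 1] + ltDD[k - 1]
            if c > bv:
                bv, bs = c, nds[k - 1]
            ndv[k] = bv
            nds[k] = bs

        for k in range(L):
            vm[k] = nmv[k]
            vi[k] = niv[k]
            vd[k] = ndv[k]
            sm[k] = nms[k]
            si[k] = nis[k]
            sd[k] = nds[k]
            sc = vm[k] + ltexit[k]
            if sc > best:
                best = sc
                best_s = sm[k]
                best_e = i

    return best, best_s, best_e


@njit(cache=True)
def sw_affine(S, gap_open, gap_extend):
    """Local alignment over a precomputed column-pair score matrix.

    Affine gaps (``gap_open`` charged for the first gapped column,
    ``gap_extend`` for each further one).  Returns
    ``(score, a_start, a_end, b_start, b_end, n_aligned_columns)`` with
    0-based inclusive coordinates; all -1 when the best score is 0.
    """
    La, Lb = S.shape
    NEG = -1e30
    M = np.zeros((La + 1, Lb + 1))
    X = np.full((La + 1, Lb + 1), NEG)  # gap in b (consume a)
    Y = np.full((La + 1, Lb + 1), NEG)  # gap in a (consume b)
    # pointers: pm 0=start here, 1=diag from M, 2=diag from X, 3=diag from Y
    #           px/py 1=open from M, 2=extend, 3=open from the other gap state
    pm = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    px = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    py = np.zeros((La + 1, Lb + 1), dtype=np.int8)

    best = 0.0
    bi = -1
    bj = -1
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            v = M[i - 1, j] - gap_open
            t = 1
            if X[i - 1, j] - gap_extend > v:
                v = X[i - 1, j] - gap_extend
                t = 2
            if Y[i - 1, j] - gap_open > v:
                v = Y[i - 1, j] - gap_open
                t = 3
            X[i, j] = v
            px[i, j] = t

            v = M[i, j - 1] - gap_open
            t = 1
            if Y[i, j - 1] - gap_extend > v:
                v = Y[i, j - 1] - gap_extend
                t = 2
            if X[i, j - 1] - gap_open > v:
                v = X[i, j - 1] - gap_open
                t = 3
            Y[i, j] = v
            py[i, j] = t

            d = S[i - 1, j - 1]
            v = d  # start a fresh alignment at this pair
            t = 0
            if M[i - 1, j - 1] + d > v:
                v = M[i - 1, j - 1] + d
                t = 1
            if X[i - 1, j - 1] + d > v:
                v = X[i - 1, j - 1] + d
                t = 2
            if Y[i - 1, j - 1] + d > v:
                v = Y[i - 1, j - 1] + d
                t = 3
            if v < 0.0:
                v = 0.0
            M[i, j] = v
            pm[i, j] = t
            if v > best:
                best = v
                bi = i
                bj = j

    if bi < 0:
        return 0.0, -1, -1, -1, -1, 0

    i, j = bi, bj
    state = 0  # 0 M, 1 X, 2 Y
    ncols = 0
    while True:
        if state == 0:
            t = pm[i, j]
            ncols += 1
            i -= 1
            j -= 1
            if t == 0:
                break
            state = 0 if t == 1 else (1 if t == 2 else 2)
        elif state == 1:
            t = px[i, j]
            i -= 1
            state = 1 if t == 2 else (0 if t == 1 else 2)
        else:
            t = py[i, j]
            j -= 1
            state = 2 if t == 2 else (0 if t == 1 else 1)
    return best, i, bi - 1, j, bj - 1, ncols


@njit(cache=True)
def nw_affine_moves(S, gap_open, gap_extend):
    """Global alignment over a column-pair score matrix; returns the moves.

    Moves are encoded 0 = diagonal, 1 = consume a only (gap in b),
    2 = consume b only, listed from the start of the alignment.  End gaps
    are charged like internal ones.
    """
    La, Lb = S.shape
    NEG = -1e30
    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)
    Y = np.full((La + 1, Lb + 1), NEG)
    pm = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 1 from M, 2 from X, 3 from Y
    px = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    py = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    M[0, 0] = 0.0

    for i in range(La + 1):
        for j in range(Lb + 1):
            if i == 0 and j == 0:
                continue
            if i > 0:
                v = M[i - 1, j] - gap_open
                t = 1
                if X[i - 1, j] - gap_extend > v:
                    v = X[i - 1, j] - gap_extend
                    t = 2
                if Y[i - 1, j] - gap_open > v:
                    v = Y[i - 1, j] - gap_open
                    t = 3
                X[i, j] = v
                px[i, j] = t
            if j > 0:
                v = M[i, j - 1] - gap_open
                t = 1
                if Y[i, j - 1] - gap_extend > v:
                    v = Y[i, j - 1] - gap_extend
                    t = 2
                if X[i, j - 1] - gap_open > v:
                    v = X[i, j - 1] - gap_open
                    t = 3
                Y[i, j] = v
                py[i, j] = t
            if i > 0 and j > 0:
                d = S[i - 1, j - 1]
                v = M[i - 1, j - 1] + d
                t = 1
                if X[i - 1, j - 1] + d > v:
                    v = X[i - 1, j - 1] + d
                    t = 2
                if Y[i - 1, j - 1] + d > v:
                    v = Y[i - 1, j - 1] + d
                    t = 3
                M[i, j] = v
                pm[i, j] = t

    moves = np.empty(La + Lb, dtype=np.int8)
    nmov = 0
    i, j = La, Lb
    state = 0
    bestv = M[i, j]
    if X[i, j] > bestv:
        bestv = X[i, j]
        state = 1
    if Y[i, j] > bestv:
        state = 2
    while i > 0 or j > 0:
        if state == 0:
            t = pm[i, j]
            moves[nmov] = 0
            nmov += 1
            i -= 1
            j -= 1
            state = 0 if t == 1 else (1 if t == 2 else 2)
        elif state == 1:
            t = px[i, j]
            moves[nmov] = 1
            nmov += 1
            i -= 1
            state = 1 if t == 2 else (0 if t == 1 else 2)
        else:
            t = py[i, j]
            moves[nmov] = 2
            nmov += 1
            j -= 1
            state = 2 if t == 2 else (0 if t == 1 else 1)
    return moves[:nmov][::-1].copy()
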