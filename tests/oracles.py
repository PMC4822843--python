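"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives a quantity by exhaustive enumeration or a naive
textbook algorithm, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

from periscan.constants import AMINO_ACIDS


def enumerate_forward(model, seq: str) -> float:
    """Sum over every (start, entry, state path) of path odds; log2 bits.

    Mirrors the scoring definition (uniform 1/(n+1) start prior, entry and
    exit on match states) by explicit recursion — exponential, toy only.
    """
    x = [AMINO_ACIDS.index(c) for c in seq]
    n = len(x)
    L = model.length
    (Eodds, iodds, tMM, tMI, tMD, tIM, tII, tDM, tDD, entry, texit) = model._odds_params()
    total = 0.0

    def rec(state, k, p, odds, i0):
        nonlocal total
        if state == "M":
            total += odds * texit[k]
            if k + 1 < L:
                if i0 + p < n:
                    rec("M", k + 1, p + 1, odds * tMM[k] * Eodds[k + 1, x[i0 + p]], i0)
                rec("D", k + 1, p, odds * tMD[k], i0)
            if i0 + p < n:
                rec("I", k, p + 1, odds * tMI[k] * iodds[x[i0 + p]], i0)
        elif state == "I":
            if k + 1 < L and i0 + p < n:
                rec("M", k + 1, p + 1, odds * tIM[k] * Eodds[k + 1, x[i0 + p]], i0)
            if i0 + p < n:
                rec("I", k, p + 1, odds * tII[k] * iodds[x[i0 + p]], i0)
        else:  # D
            if k + 1 < L:
                if i0 + p < n:
                    rec("M", k + 1, p + 1, odds * tDM[k] * Eodds[k + 1, x[i0 + p]], i0)
                rec("D", k + 1, p, odds * tDD[k], i0)

    for i0 in range(n):
        for k0 in range(L):
            rec("M", k0, 1, entry[k0] * Eodds[k0, x[i0]], i0)
    return math.log2(total) - math.log2(n + 1)


def brute_force_greedy(sets: list[tuple[str, frozenset]]) -> list[str]:
    """Reference greedy max-coverage with the stated tie rules.

    ``sets`` is a list of (representative_id, member frozenset) *after*
    subset/duplicate removal.  Ties: larger raw set, then smaller id.
    """
    universe = set()
    for _, m in sets:
        universe |= m
    working: set = set()
    order: list[str] = []
    remaining = list(sets)
    while working != universe:
        scored = [
            (len(m - working), len(m), rid, m)
            for rid, m in remaining
            if len(m - working) > 0
        ]
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        gain, _, rid, m = scored[0]
        order.append(rid)
        working |= m
        remaining = [(r, mm) for r, mm in remaining if r != rid]
    return order


def best_k_coverage(sets: list[frozenset], k: int) -> int:
    """Exhaustive maximum coverage achievable by any k sets."""
    from itertools import combinations

    best = 0
    for combo in combinations(sets, min(k, len(sets))):
        cov = set()
        for m in combo:
            cov |= m
        best = max(best, len(cov))
    return best


def naive_upgma(dist: np.ndarray) -> list[tuple[frozenset, float]]:
    """Textbook O(n^3) UPGMA; returns merges as (leaf-set, height) pairs.

    Heights are half the merge distance (ultrametric node heights), so the
    result can be compared against cophenetic structure from any linkage
    implementation.
    """
    n = dist.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters[i] | clusters[j]
        merges.append((merged, dij / 2.0))
        ni, nj = len(clusters[i]), len(clusters[j])
        del clusters[i], clusters[j]
        new = {}
        for (a, b), v in d.items():
            if i in (a, b) or j in (a, b):
                continue
            new[(a, b)] = v
        for k in clusters:
            da = d[(min(i, k), max(i, k))]
            db = d[(min(j, k), max(j, k))]
            new[(min(nxt, k), max(nxt, k))] = (ni * da + nj * db) / (ni + nj)
        clusters[nxt] = merged
        d = new
        nxt += 1
    return merges
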