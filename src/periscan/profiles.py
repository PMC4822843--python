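"""Profile models of sequence families: construction, calibration, scanning.

The family model is a profile hidden Markov model in the usual
match/insert/delete layout.  Match emissions come from Henikoff
position-based weighted counts blended with background pseudocounts;
transitions from weighted path counts with Laplace smoothing.  Scoring is
fully local (entry into and exit from any match state), as sensor domains
occur inside larger proteins:

* ``forward_score`` — log2 of the path-summed emission odds against the
  background null, with a uniform prior over start positions; this is the
  bit score used for detection.
* ``calibrate`` — fits a Gumbel to forward scores of random background
  sequences; ``E = n_targets * P(S > s)`` converts scores to E-values.
* ``scan`` — detects domain envelopes per protein per model by iterative
  Viterbi segmentation, thresholded on sequence- and domain-level E-values.
* ``profile_profile_compare`` — local alignment of two models' match-column
  emission distributions, calibrated by column shuffling.  Its probability
  score is defined operationally as ``100 * (1 - P)`` with ``P`` the
  calibrated P-value of the comparison score: remote-homology thresholds
  quoted on a 0-100 probability scale apply to *this* statistic throughout
  the package (a posterior from a full profile-profile HMM would need
  secondary-structure terms that are out of scope here).
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.stats import gumbel_r

from . import _dp
from .constants import AMINO_ACIDS, BACKGROUND, aa_to_indices

__all__ = [
    "Alignment",
    "ProfileModel",
    "DomainHit",
    "ProfileProfileHit",
    "progressive_align",
    "build_profile",
    "forward_score",
    "viterbi_envelope",
    "calibrate",
    "fit_gumbel",
    "scan",
    "profile_profile_compare",
    "merge_clusters",
    "model_to_json",
    "model_from_json",
]

N_AA = len(AMINO_ACIDS)
GAP = "-"

#: Local-exit probability reserved from each internal match state.
DEFAULT_EXIT_PROB = 0.05


# ---------------------------------------------------------------------------
# alignments


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment: equal-length gapped rows plus a match mask."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    match_mask: tuple[bool, ...] = ()
    source_cluster: str = ""

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows differ in length")
        if self.match_mask and len(self.match_mask) != width:
            raise ValueError("match mask length != alignment width")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)


def _kmer_profile(seq: str, k: int = 3) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    return prof


def _kmer_distance(a: dict[str, int], b: dict[str, int]) -> float:
    shared = sum(min(c, b.get(m, 0)) for m, c in a.items())
    denom = min(sum(a.values()), sum(b.values()))
    return 1.0 - shared / denom if denom else 1.0


def _column_freqs(rows: list[str], weights: np.ndarray | None = None) -> np.ndarray:
    """Per-column residue frequencies (gaps excluded), shape (width, 20)."""
    n = len(rows)
    w = np.ones(n) if weights is None else weights
    width = len(rows[0])
    freq = np.zeros((width, N_AA))
    for r, row in enumerate(rows):
        for c, ch in enumerate(row):
            if ch != GAP:
                freq[c, AMINO_ACIDS.index(ch)] += w[r]
    totals = freq.sum(axis=1, keepdims=True)
    totals[totals == 0.0] = 1.0
    return freq / totals


_BLOSUM62 = None


def _blosum62() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        m = np.zeros((N_AA, N_AA))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = mat[a, b]
        _BLOSUM62 = m
    return _BLOSUM62


def _merge_alignments(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    """Profile-profile global alignment of two gapped row blocks."""
    fa = _column_freqs(rows_a)
    fb = _column_freqs(rows_b)
    S = fa @ _blosum62() @ fb.T
    # de-weight columns that are mostly gaps on either side
    occ_a = np.array([
        sum(1 for r in rows_a if r[c] != GAP) / len(rows_a) for c in range(len(rows_a[0]))
    ])
    occ_b = np.array([
        sum(1 for r in rows_b if r[c] != GAP) / len(rows_b) for c in range(len(rows_b[0]))
    ])
    S = S * occ_a[:, None] * occ_b[None, :]
    moves = _dp.nw_affine_moves(S, gap_open, gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for mv in moves:
        if mv == 0:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[ia])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[ib])
            ia += 1
            ib += 1
        elif mv == 1:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[ia])
            for r in range(len(rows_b)):
                out_b[r].append(GAP)
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append(GAP)
            for r, row in enumerate(rows_b):
                out_b[r].append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_align(
    sequences: dict[str, str],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    kmer: int = 3,
) -> Alignment:
    """Progressive multiple alignment with a UPGMA k-mer guide tree.

    Pairwise k-mer distances feed a UPGMA joining order; profiles are
    merged by global profile-profile alignment under BLOSUM62 expected
    scores with affine gaps.  Deterministic: ties in the joining order are
    broken by node ids.
    """
    ids = sorted(sequences)
    if not ids:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return Alignment((ids[0],), (sequences[ids[0]],))
    profs = {i: _kmer_profile(sequences[i], kmer) for i in ids}
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            dist[(a, b)] = _kmer_distance(profs[a], profs[b])

    def d(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    # UPGMA agglomeration over cluster (members, rows) nodes
    nodes: dict[str, tuple[list[str], list[str]]] = {
        i: ([i], [sequences[i]]) for i in ids
    }
    cluster_d: dict[tuple[str, str], float] = dict(dist)
    counter = 0
    while len(nodes) > 1:
        pair = min(
            (
                (cluster_d[(a, b)] if (a, b) in cluster_d else cluster_d[(b, a)], a, b)
                for i, a in enumerate(sorted(nodes))
                for b in sorted(nodes)[i + 1 :]
            ),
        )
        _, a, b = pair
        mem_a, rows_a = nodes.pop(a)
        mem_b, rows_b = nodes.pop(b)
        new_a, new_b = _merge_alignments(rows_a, rows_b, gap_open, gap_extend)
        new_id = f"@{counter}"
        counter += 1
        for other in list(nodes):
            mem_o = nodes[other][0]
            da = _avg_dist(cluster_d, mem_a, mem_o, dist)
            db = _avg_dist(cluster_d, mem_b, mem_o, dist)
            na, nb = len(mem_a), len(mem_b)
            cluster_d[(new_id, other)] = (na * da + nb * db) / (na + nb)
        nodes[new_id] = (mem_a + mem_b, new_a + new_b)
        cluster_d = {
            k: v for k, v in cluster_d.items() if k[0] in nodes or k[1] in nodes
        }

    members, rows = next(iter(nodes.values()))
    order = sorted(range(len(members)), key=lambda r: members[r])
    return Alignment(
        tuple(members[r] for r in order), tuple(rows[r] for r in order)
    )


def _avg_dist(cluster_d, mem_a, mem_o, leaf_dist) -> float:
    total = 0.0
    for x in mem_a:
        for y in mem_o:
            total += leaf_dist[(x, y)] if (x, y) in leaf_dist else leaf_dist[(y, x)]
    return total / (len(mem_a) * len(mem_o))


# ---------------------------------------------------------------------------
# profile model


@dataclass(frozen=True)
class ProfileModel:
    model_id: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,)
    tMM: np.ndarray  # (L,) last entry unused
    tMI: np.ndarray
    tMD: np.ndarray
    tIM: np.ndarray
    tII: np.ndarray
    tDM: np.ndarray
    tDD: np.ndarray
    background: np.ndarray  # (20,)
    exit_prob: float = DEFAULT_EXIT_PROB
    mu: float | None = None  # Gumbel location (bits)
    lambda_g: float | None = None  # Gumbel inverse scale (1/bits)
    n_sequences: int = 0

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.mu is not None and self.lambda_g is not None

    def validate(self, tol: float = 1e-9) -> None:
        L = self.length
        if L < 1:
            raise ValueError("model must have at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol):
            raise ValueError("match emissions do not normalise")
        for arr in (self.insert_emissions, self.background):
            if abs(arr.sum() - 1.0) > tol:
                raise ValueError("emission distribution does not normalise")
        out_m = self.tMM[:-1] + self.tMI[:-1] + self.tMD[:-1]
        if L > 1 and not np.allclose(out_m, 1.0, atol=tol):
            raise ValueError("match transitions do not normalise")
        if not np.allclose(self.tIM + self.tII, 1.0, atol=tol):
            raise ValueError("insert transitions do not normalise")
        out_d = (self.tDM + self.tDD)[1:-1]
        if L > 2 and not np.allclose(out_d, 1.0, atol=tol):
            raise ValueError("delete transitions do not normalise")
        if self.lambda_g is not None and self.lambda_g <= 0:
            raise ValueError("calibrated lambda must be positive")

    # scoring parameter bundles -------------------------------------------

    def _odds_params(self):
        L = self.length
        tau = self.exit_prob
        scale = np.full(L, 1.0 - tau)
        scale[L - 1] = 0.0  # last match state must exit
        texit = np.full(L, tau)
        texit[L - 1] = 1.0
        entry = np.full(L, 1.0 / L)
        Eodds = self.match_emissions / self.background[None, :]
        iodds = self.insert_emissions / self.background
        return (
            Eodds,
            iodds,
            self.tMM * scale,
            self.tMI * scale,
            self.tMD * scale,
            self.tIM,
            self.tII,
            self.tDM,
            self.tDD,
            entry,
            texit,
        )

    def _log_params(self):
        pars = self._odds_params()
        with np.errstate(divide="ignore"):
            return tuple(np.log2(p) for p in pars)


def henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based sequence weights, scaled to sum to the row count."""
    n = len(rows)
    width = len(rows[0])
    w = np.zeros(n)
    for c in range(width):
        col = [row[c] for row in rows]
        residues = [ch for ch in col if ch != GAP]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for ch in residues:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for i, ch in enumerate(col):
            if ch != GAP:
                w[i] += 1.0 / (r * counts[ch])
    if w.sum() == 0.0:
        return np.ones(n)
    return w * n / w.sum()


def build_profile(
    alignment: Alignment,
    model_id: str = "",
    match_fraction: float = 0.5,
    pseudocount_weight: float = 1.5,
    transition_pseudocount: float = 1.0,
    background: np.ndarray = BACKGROUND,
    exit_prob: float = DEFAULT_EXIT_PROB,
) -> ProfileModel:
    """Build a profile HMM from a multiple alignment.

    Columns whose non-gap fraction is at least ``match_fraction`` become
    match states.  Emissions are Henikoff-weighted counts plus
    ``pseudocount_weight * background`` — a fixed-mass pseudocount whose
    influence therefore decays as the (weighted) number of observations
    grows.  Transitions are weighted path counts with Laplace smoothing of
    ``transition_pseudocount`` per target state.  Insert emissions are the
    background itself.
    """
    rows = list(alignment.rows)
    n = len(rows)
    width = alignment.width
    if alignment.match_mask:
        mask = list(alignment.match_mask)
    else:
        mask = [
            sum(1 for row in rows if row[c] != GAP) / n >= match_fraction
            for c in range(width)
        ]
    match_cols = [c for c in range(width) if mask[c]]
    L = len(match_cols)
    if L == 0:
        raise ValueError("alignment has no match columns")

    w = henikoff_weights(rows)

    # emissions
    em = np.zeros((L, N_AA))
    for k, c in enumerate(match_cols):
        for r, row in enumerate(rows):
            ch = row[c]
            if ch != GAP:
                em[k, AMINO_ACIDS.index(ch)] += w[r]
    em = em + pseudocount_weight * background[None, :]
    em /= em.sum(axis=1, keepdims=True)

    # transition counts from per-row state paths
    cMM = np.zeros(L)
    cMI = np.zeros(L)
    cMD = np.zeros(L)
    cIM = np.zeros(L)
    cII = np.zeros(L)
    cDM = np.zeros(L)
    cDD = np.zeros(L)
    for r, row in enumerate(rows):
        wr = w[r]
        for k in range(L - 1):
            c0, c1 = match_cols[k], match_cols[k + 1]
            src_match = row[c0] != GAP
            n_ins = sum(1 for c in range(c0 + 1, c1) if not mask[c] and row[c] != GAP)
            dst_match = row[c1] != GAP
            if n_ins == 0:
                if src_match and dst_match:
                    cMM[k] += wr
                elif src_match:
                    cMD[k] += wr
                elif dst_match:
                    cDM[k] += wr
                else:
                    cDD[k] += wr
            else:
                # inserts hang off the source node; delete-adjacent inserts
                # are attributed to the source state's insert track too
                cMI[k] += wr if src_match else 0.0
                cII[k] += wr * (n_ins - 1)
                cIM[k] += wr
                if not src_match:
                    cDM[k] += wr  # approximate D..I..M as D->M for the skeleton
    tp = transition_pseudocount
    tMM = np.ones(L)
    tMI = np.zeros(L)
    tMD = np.zeros(L)
    for k in range(L - 1):
        tot = cMM[k] + cMI[k] + cMD[k] + 3 * tp
        tMM[k] = (cMM[k] + tp) / tot
        tMI[k] = (cMI[k] + tp) / tot
        tMD[k] = (cMD[k] + tp) / tot
    tIM = np.empty(L)
    tII = np.empty(L)
    for k in range(L):
        tot = cIM[k] + cII[k] + 2 * tp
        tIM[k] = (cIM[k] + tp) / tot
        tII[k] = (cII[k] + tp) / tot
    tDM = np.ones(L)
    tDD = np.zeros(L)
    for k in range(1, L - 1):
        tot = cDM[k] + cDD[k] + 2 * tp
        tDM[k] = (cDM[k] + tp) / tot
        tDD[k] = (cDD[k] + tp) / tot

    model = ProfileModel(
        model_id=model_id or (alignment.source_cluster or "model"),
        match_emissions=em,
        insert_emissions=background.copy(),
        tMM=tMM, tMI=tMI, tMD=tMD, tIM=tIM, tII=tII, tDM=tDM, tDD=tDD,
        background=background.copy(),
        exit_prob=exit_prob,
        n_sequences=n,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# scoring


def forward_score(model: ProfileModel, sequence: str) -> float:
    """Forward bit score of a sequence against the model.

    log2 of the path-summed odds with a uniform 1/(n+1) prior over start
    positions.  An empty sequence has no emitting path and scores -inf.
    """
    if not sequence:
        return -math.inf
    x = aa_to_indices(sequence)
    pars = model._odds_params()
    raw = _dp.forward_bits(x, *pars)
    return raw - math.log2(len(sequence) + 1)


def viterbi_envelope(model: ProfileModel, sequence: str) -> tuple[float, int, int]:
    """Best-path bit score and its 1-based envelope on the sequence."""
    if not sequence:
        return -math.inf, 0, 0
    x = aa_to_indices(sequence)
    pars = model._log_params()
    score, s, e = _dp.viterbi_best(x, *pars)
    return score - math.log2(len(sequence) + 1), s + 1, e + 1


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda_g = 1/scale)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.std(scores) < 1e-9:
        raise ValueError("degenerate score distribution; cannot fit Gumbel")
    loc, scale = gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def calibrate(
    model: ProfileModel,
    n_random: int = 300,
    random_length: int = 200,
    rng_seed: int = 0,
    composition: np.ndarray | None = None,
    fix_lambda_log2: bool = True,
) -> ProfileModel:
    """Fit a Gumbel law to forward scores of random background sequences.

    ``composition`` defaults to the model background; pass the residue
    composition of the target universe when it differs.  Returns a new
    model carrying (mu, lambda_g).

    By default the Gumbel scale is fixed at ``1/ln 2``: the high tail of a
    log2-odds forward score decays like ``2**(-s)``, and a free fit driven
    by the bulk of the null distribution decays faster than that tail,
    underestimating P-values by orders of magnitude exactly where the
    detection thresholds live.  Set ``fix_lambda_log2=False`` for a free
    two-parameter fit.
    """
    if n_random < 200:
        raise ValueError("n_random must be >= 200 for a stable fit")
    comp = model.background if composition is None else composition
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=rng_seed, spawn_key=(zlib.crc32(model.model_id.encode()),))
    )
    scores = np.empty(n_random)
    for i in range(n_random):
        idx = rng.choice(N_AA, size=random_length, p=comp)
        seq = "".join(AMINO_ACIDS[j] for j in idx)
        scores[i] = forward_score(model, seq)
    if fix_lambda_log2:
        if np.std(scores) < 1e-9:
            raise ValueError("degenerate score distribution; cannot calibrate")
        loc, scale = gumbel_r.fit(scores, fscale=1.0 / math.log(2.0))
        mu, lam = float(loc), float(1.0 / scale)
    else:
        mu, lam = fit_gumbel(scores)
    return replace(model, mu=mu, lambda_g=lam)


def score_pvalue(model: ProfileModel, score: float) -> float:
    """Gumbel survival P(S > score) under the model's calibration."""
    if not model.calibrated:
        raise ValueError(f"model {model.model_id} is not calibrated")
    return float(gumbel_r.sf(score, loc=model.mu, scale=1.0 / model.lambda_g))


def score_evalue(model: ProfileModel, score: float, n_targets: int) -> float:
    return n_targets * score_pvalue(model, score)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    model_id: str
    start: int  # 1-based inclusive envelope
    end: int
    bitscore: float
    seq_evalue: float
    dom_evalue: float


def scan(
    models: list[ProfileModel],
    sequences: dict[str, str],
    seq_evalue_max: float = 1e-3,
    dom_evalue_max: float = 1e-3,
    max_domains: int = 8,
) -> list[DomainHit]:
    """Scan a sequence universe with calibrated models.

    Per protein and model, the full-sequence forward score gives the
    sequence E-value; domain envelopes are found by iterative Viterbi
    segmentation (best path span, then recursion into the flanks), each
    envelope rescored by forward on its own span for the domain E-value.
    Hits failing either threshold are dropped.  Overlapping hits from
    different models are all reported; resolution belongs to the census.
    """
    for m in models:
        if not m.calibrated:
            raise ValueError(f"model {m.model_id} is not calibrated")
    n_targets = len(sequences)
    hits: list[DomainHit] = []
    for pid in sorted(sequences):
        seq = sequences[pid]
        if not seq:
            continue
        for model in models:
            s_fwd = forward_score(model, seq)
            seq_e = score_evalue(model, s_fwd, n_targets)
            if seq_e > seq_evalue_max:
                continue
            segments = [(1, len(seq))]
            found = 0
            while segments and found < max_domains:
                lo, hi = segments.pop(0)
                if hi - lo + 1 < 10:
                    continue
                sub = seq[lo - 1 : hi]
                v_bits, vs, ve = viterbi_envelope(model, sub)
                if vs <= 0:
                    continue
                env_start, env_end = lo + vs - 1, lo + ve - 1
                env_bits = forward_score(model, seq[env_start - 1 : env_end])
                dom_e = score_evalue(model, env_bits, n_targets)
                if dom_e <= dom_evalue_max:
                    hits.append(
                        DomainHit(pid, model.model_id, env_start, env_end,
                                  env_bits, seq_e, dom_e)
                    )
                    found += 1
                    segments.append((lo, env_start - 1))
                    segments.append((env_end + 1, hi))
    return hits


# ---------------------------------------------------------------------------
# profile-profile comparison


@dataclass(frozen=True)
class ProfileProfileHit:
    model_a: str
    model_b: str
    score: float  # bits
    evalue: float
    probability: float  # 0..100, operational definition (see module doc)
    a_start: int  # 1-based aligned match-column ranges
    a_end: int
    b_start: int
    b_end: int
    n_columns: int

    def coverage_of(self, length_a: int, length_b: int) -> float:
        """Aligned columns over the shorter model."""
        return self.n_columns / min(length_a, length_b)


def _pp_score_matrix(a: ProfileModel, b: ProfileModel) -> np.ndarray:
    q = a.background
    return np.log2((a.match_emissions / q[None, :]) @ b.match_emissions.T)


def profile_profile_compare(
    a: ProfileModel,
    b: ProfileModel,
    gap_open: float = 7.0,
    gap_extend: float = 1.0,
    n_shuffles: int = 100,
    rng_seed: int = 0,
    n_comparisons: int = 1,
) -> ProfileProfileHit:
    """Local alignment of two profiles' match-emission columns.

    The column-pair score is ``log2 sum_x p_a(x) p_b(x) / q(x)``; the
    alignment is Smith-Waterman with affine gaps over match columns only.
    Significance comes from re-aligning against column-shuffled copies of
    ``b`` and fitting a Gumbel: ``E = n_comparisons * P``, and the
    probability score is ``100 * (1 - P)``.
    """
    if a.length == 0 or b.length == 0:
        raise ValueError("cannot compare zero-length models")
    S = _pp_score_matrix(a, b)
    score, as_, ae, bs, be, ncols = _dp.sw_affine(S, gap_open, gap_extend)

    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=rng_seed,
            spawn_key=(zlib.crc32(a.model_id.encode()), zlib.crc32(b.model_id.encode())),
        )
    )
    null_scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(b.length)
        null_scores[i] = _dp.sw_affine(S[:, perm], gap_open, gap_extend)[0]
    if np.std(null_scores) < 1e-12:
        pval = 1.0
    else:
        loc, scale = gumbel_r.fit(null_scores)
        pval = float(gumbel_r.sf(score, loc=loc, scale=scale))
    return ProfileProfileHit(
        a.model_id, b.model_id, float(score), n_comparisons * pval,
        100.0 * (1.0 - pval), as_ + 1, ae + 1, bs + 1, be + 1, ncols,
    )


def all_vs_all_profiles(
    models: list[ProfileModel],
    rng_seed: int = 0,
    n_shuffles: int = 100,
    include_self: bool = False,
    **kwargs,
) -> list[ProfileProfileHit]:
    """Directional profile-profile hits for every ordered model pair."""
    n_comp = max(1, len(models) - 1)
    hits = []
    for a in models:
        for b in models:
            if a.model_id == b.model_id and not include_self:
                continue
            hits.append(
                profile_profile_compare(
                    a, b, rng_seed=rng_seed, n_shuffles=n_shuffles,
                    n_comparisons=n_comp, **kwargs,
                )
            )
    return hits


def merge_clusters(
    alignments: dict[str, Alignment],
    models: dict[str, ProfileModel],
    probability_min: float = 90.0,
    coverage_min: float = 0.6,
    min_bits_per_column: float = 2.0,
    rng_seed: int = 0,
    n_shuffles: int = 100,
    max_rounds: int = 3,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    **build_kwargs,
) -> tuple[dict[str, Alignment], dict[str, ProfileModel]]:
    """Merge clusters whose models are reciprocally near-identical.

    Two models merge when both directional comparisons have probability
    above ``probability_min``, aligned-column coverage (aligned columns
    over the shorter model) at least ``coverage_min``, and alignment
    strength of at least ``min_bits_per_column`` bits per aligned column.
    The last condition is what separates fragments of one family (whose
    column distributions nearly coincide, ~2.5+ bits/column) from distinct
    families of the same superfamily (remote but significant, well under
    2 bits/column): the probability score saturates for any significant
    relationship and cannot make that distinction by itself.

    Linked groups are merged transitively by profile-profile alignment of
    their MSAs, models rebuilt, and the process repeated to a fixed point
    (bounded by ``max_rounds``).  The merged id concatenates the member ids
    with '+' in sorted order, so the fixed point is order-independent.
    """
    aligns = dict(alignments)
    mods = dict(models)
    for _ in range(max_rounds):
        ids = sorted(mods)
        if len(ids) < 2:
            break
        n_comp = max(1, len(ids) - 1)
        link: dict[str, set[str]] = {i: set() for i in ids}
        for i, ia in enumerate(ids):
            for ib in ids[i + 1 :]:
                h_ab = profile_profile_compare(
                    mods[ia], mods[ib], rng_seed=rng_seed,
                    n_shuffles=n_shuffles, n_comparisons=n_comp,
                )
                h_ba = profile_profile_compare(
                    mods[ib], mods[ia], rng_seed=rng_seed,
                    n_shuffles=n_shuffles, n_comparisons=n_comp,
                )
                cov = min(
                    h_ab.coverage_of(mods[ia].length, mods[ib].length),
                    h_ba.coverage_of(mods[ia].length, mods[ib].length),
                )
                cpc = min(
                    h_ab.score / max(1, h_ab.n_columns),
                    h_ba.score / max(1, h_ba.n_columns),
                )
                if (
                    h_ab.probability > probability_min
                    and h_ba.probability > probability_min
                    and cov >= coverage_min
                    and cpc >= min_bits_per_column
                ):
                    link[ia].add(ib)
                    link[ib].add(ia)
        # connected components of the link graph
        groups: list[list[str]] = []
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                continue
            stack, comp = [i], []
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                comp.append(u)
                stack.extend(link[u] - seen)
            groups.append(sorted(comp))
        if all(len(g) == 1 for g in groups):
            break
        new_aligns: dict[str, Alignment] = {}
        for g in groups:
            if len(g) == 1:
                new_aligns[g[0]] = aligns[g[0]]
                continue
            rows_ids = list(aligns[g[0]].ids)
            rows = list(aligns[g[0]].rows)
            for other in g[1:]:
                ob = aligns[other]
                rows, new_b = _merge_alignments(rows, list(ob.rows), gap_open, gap_extend)
                rows = rows + new_b
                rows_ids = rows_ids + list(ob.ids)
            new_id = "+".join(sorted(set(sum((gid.split("+") for gid in g), []))))
            new_aligns[new_id] = Alignment(
                tuple(rows_ids), tuple(rows), source_cluster=new_id
            )
        aligns = new_aligns
        mods = {
            mid: build_profile(aln, model_id=mid, **build_kwargs)
            for mid, aln in aligns.items()
        }
    return aligns, mods


# ---------------------------------------------------------------------------
# serialization


def model_to_json(model: ProfileModel) -> str:
    payload = {
        "model_id": model.model_id,
        "alphabet": AMINO_ACIDS,
        "length": model.length,
        "match_emissions": model.match_emissions.tolist(),
        "insert_emissions": model.insert_emissions.tolist(),
        "transitions": {
            name: getattr(model, name).tolist()
            for name in ("tMM", "tMI", "tMD", "tIM", "tII", "tDM", "tDD")
        },
        "background": model.background.tolist(),
        "exit_prob": model.exit_prob,
        "calibration": (
            {"mu": model.mu, "lambda_g": model.lambda_g} if model.calibrated else None
        ),
        "n_sequences": model.n_sequences,
    }
    return json.dumps(payload, indent=1)


def model_from_json(text: str) -> ProfileModel:
    d = json.loads(text)
    for key in ("model_id", "match_emissions", "transitions", "background"):
        if key not in d:
            raise ValueError(f"model JSON missing field: {key}")
    cal = d.get("calibration") or {}
    model = ProfileModel(
        model_id=d["model_id"],
        match_emissions=np.asarray(d["match_emissions"], dtype=float),
        insert_emissions=np.asarray(d["insert_emissions"], dtype=float),
        tMM=np.asarray(d["transitions"]["tMM"], dtype=float),
        tMI=np.asarray(d["transitions"]["tMI"], dtype=float),
        tMD=np.asarray(d["transitions"]["tMD"], dtype=float),
        tIM=np.asarray(d["transitions"]["tIM"], dtype=float),
        tII=np.asarray(d["transitions"]["tII"], dtype=float),
        tDM=np.asarray(d["transitions"]["tDM"], dtype=float),
        tDD=np.asarray(d["transitions"]["tDD"], dtype=float),
        background=np.asarray(d["background"], dtype=float),
        exit_prob=float(d.get("exit_prob", DEFAULT_EXIT_PROB)),
        mu=cal.get("mu"),
        lambda_g=cal.get("lambda_g"),
        n_sequences=int(d.get("n_sequences", 0)),
    )
    model.validate(tol=1e-6)
    return model


def save_model(model: ProfileModel, path: str | Path) -> None:
    Path(path).write_text(model_to_json(model))


def load_model(path: str | Path) -> ProfileModel:
    return model_from_json(Path(path).read_text())
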