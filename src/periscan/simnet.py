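"""All-vs-all sequence comparison and the reciprocal-similarity network.

Candidate sensor regions are compared all-against-all by optimal local
(Smith-Waterman) alignment under BLOSUM62 with affine gaps; raw scores are
converted to bit scores with Karlin-Altschul constants and to E-values with
the database size.  Two regions are connected in the similarity graph iff
*both* directional hits pass the thresholds (E-value < 1e-10 and query
coverage > 95% by default) — reciprocity is structural.  Connected
components of the graph are the sequence clusters; clusters with at least
ten members go on to model building.

Redundancy reduction follows the greedy incremental convention: sequences
sorted by length (longest first), each joining the first retained sequence
it matches at >= the identity threshold, identity counted over the shorter
sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .constants import KA_K, KA_LAMBDA

__all__ = [
    "SimilarityHit",
    "Cluster",
    "local_align",
    "evalue",
    "all_vs_all",
    "reduce_redundancy",
    "build_graph",
    "components",
    "write_hits_tsv",
    "read_hits_tsv",
    "write_clusters_tsv",
]


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    query_coverage: float  # aligned query span / query length
    identity: float  # matches / alignment columns

    def as_row(self) -> tuple:
        return (
            self.query_id, self.subject_id, self.bitscore, self.evalue,
            self.query_coverage, self.identity,
        )


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: frozenset[str]
    has_labeled_member: bool = False

    def __len__(self) -> int:
        return len(self.members)


def _aligner(gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -(gap_open)
    al.extend_gap_score = -(gap_extend)
    return al


def local_align(
    a: str,
    b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, float, float, float]:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns ``(bitscore, identity, query_coverage, subject_coverage)`` where
    the bit score is ``(lambda*S - ln K)/ln 2`` with the BLOSUM62 constants
    from :mod:`periscan.constants` and identity is matches over alignment
    columns (gap columns included).  Coverage is the fraction of a
    sequence's residues sitting in gap-free (residue-residue) alignment
    columns — not the start-to-end span, which would credit arbitrarily
    long internal gaps towards coverage.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    al = _aligner(gap_open, gap_extend, "local")
    aln = al.align(a, b)[0]
    raw = aln.score
    bits = (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)

    qa = aln.aligned[0]
    sa = aln.aligned[1]
    matches = 0
    aligned_cols = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        aligned_cols += qe - qs
        for i in range(qe - qs):
            columns += 1
            if a[qs + i] == b[ss + i]:
                matches += 1
    # count gap columns between aligned blocks
    for k in range(1, len(qa)):
        columns += (qa[k][0] - qa[k - 1][1]) + (sa[k][0] - sa[k - 1][1])
    identity = matches / columns if columns else 0.0
    return bits, identity, aligned_cols / len(a), aligned_cols / len(b)


def evalue(bitscore: float, query_length: int, database_residues: int) -> float:
    """Karlin-Altschul expectation: ``E = m * n * 2**(-bits)``."""
    if query_length <= 0 or database_residues <= 0:
        raise ValueError("lengths must be positive")
    return float(query_length) * float(database_residues) * 2.0 ** (-bitscore)


def all_vs_all(
    sequences: dict[str, str],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    bitscore_min: float = 0.0,
) -> list[SimilarityHit]:
    """Directional hits for every ordered pair (self-hits omitted).

    Each unordered pair is aligned once (local alignment is symmetric up to
    the roles of query and subject); the two directional hits differ only in
    which sequence's length normalises coverage and the E-value.
    """
    ids = sorted(sequences)
    db_residues = sum(len(s) for s in sequences.values())
    hits: list[SimilarityHit] = []
    for i, qid in enumerate(ids):
        for sid in ids[i + 1 :]:
            a, b = sequences[qid], sequences[sid]
            bits, ident, cov_q, cov_s = local_align(a, b, gap_open, gap_extend)
            if bits < bitscore_min:
                continue
            hits.append(
                SimilarityHit(qid, sid, bits, evalue(bits, len(a), db_residues), cov_q, ident)
            )
            hits.append(
                SimilarityHit(sid, qid, bits, evalue(bits, len(b), db_residues), cov_s, ident)
            )
    return hits


def _shorter_identity(a: str, b: str, gap_open: float, gap_extend: float) -> float:
    """Identity as matches over the shorter sequence length (CD-HIT style)."""
    al = _aligner(gap_open, gap_extend, "local")
    aln = al.align(a, b)[0]
    matches = 0
    for (qs, qe), (ss, se) in zip(aln.aligned[0], aln.aligned[1]):
        for i in range(qe - qs):
            if a[qs + i] == b[ss + i]:
                matches += 1
    return matches / min(len(a), len(b))


def reduce_redundancy(
    sequences: dict[str, str],
    identity_threshold: float = 0.90,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[str]:
    """Greedy incremental redundancy reduction at an identity threshold.

    Sequences are processed longest first (ties broken lexicographically by
    id); each sequence joins the first retained sequence to which its
    identity — matches over the shorter length — reaches the threshold,
    otherwise it is itself retained.  Returns the retained ids in retention
    order.

    A global edit-distance bound (edlib) prunes candidate pairs first:
    matched positions cannot exceed ``shorter - (distance - overhang)``
    where ``overhang = len_a + len_b - 2*shorter``, so a pair whose edit
    distance already forces identity below the threshold skips the full
    alignment.
    """
    import edlib

    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    retained: list[str] = []
    for sid in order:
        seq = sequences[sid]
        for rid in retained:
            other = sequences[rid]
            shorter = min(len(seq), len(other))
            # matches <= shorter - max(0, dist - (len_a + len_b - 2*shorter))
            dist = edlib.align(seq, other, mode="NW", task="distance")["editDistance"]
            overhang = len(seq) + len(other) - 2 * shorter
            if (shorter - max(0, dist - overhang)) / shorter < identity_threshold:
                continue
            if _shorter_identity(seq, other, gap_open, gap_extend) >= identity_threshold:
                break
        else:
            retained.append(sid)
    return retained


def build_graph(
    hits: list[SimilarityHit],
    node_ids,
    evalue_max: float = 1e-10,
    coverage_min: float = 0.95,
) -> nx.Graph:
    """Reciprocal-similarity graph.

    Edge (a, b) exists iff hit(a→b) and hit(b→a) both have E-value strictly
    below ``evalue_max`` and query coverage strictly above ``coverage_min``
    (literal "less than" / "greater than" reading of the thresholds).
    Isolated nodes are kept so components partition the full universe.
    """
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    passing: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue < evalue_max and h.query_coverage > coverage_min:
            passing[(h.query_id, h.subject_id)] = h
    for (q, s), h in passing.items():
        if q < s and (s, q) in passing:
            g.add_edge(q, s, forward=h, backward=passing[(s, q)])
    return g


def components(
    graph: nx.Graph,
    min_size: int = 10,
    labeled_ids: set[str] | None = None,
) -> tuple[list[Cluster], list[Cluster]]:
    """Connected components as clusters.

    Returns ``(all_clusters, filtered)`` where ``filtered`` keeps clusters
    with at least ``min_size`` members and — when ``labeled_ids`` is given —
    at least one labeled member.  Cluster ids are assigned by decreasing
    size, ties broken by smallest member id.
    """
    labeled_ids = labeled_ids or set()
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    clusters = [
        Cluster(f"C{i:04d}", frozenset(c), bool(set(c) & labeled_ids))
        for i, c in enumerate(comps)
    ]
    filtered = [
        c for c in clusters
        if len(c) >= min_size and (not labeled_ids or c.has_labeled_member)
    ]
    return clusters, filtered


# ---------------------------------------------------------------------------
# I/O

HITS_COLUMNS = ["query", "subject", "bitscore", "evalue", "qcov", "identity"]


def write_hits_tsv(hits: list[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.bitscore:.4f}\t"
                f"{h.evalue:.6e}\t{h.query_coverage:.6f}\t{h.identity:.6f}\n"
            )


def read_hits_tsv(path: str | Path) -> list[SimilarityHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HITS_COLUMNS:
            missing = [c for c in HITS_COLUMNS if c not in header]
            raise ValueError(f"hits TSV missing column(s): {', '.join(missing) or header}")
        for line in fh:
            q, s, bits, ev, cov, ident = line.rstrip("\n").split("\t")
            hits.append(SimilarityHit(q, s, float(bits), float(ev), float(cov), float(ident)))
    return hits


def write_clusters_tsv(clusters: list[Cluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_id\n")
        for c in clusters:
            for m in sorted(c.members):
                fh.write(f"{c.cluster_id}\t{m}\n")


def write_edges_tsv(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(graph.edges()):
            fh.write(f"{a}\t{b}\n")
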