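"""Greedy maximum-coverage selection of representative sequences.

Each query sequence represents the set of sequences it hits above the
similarity thresholds (itself included).  After discarding represented sets
that are identical to or subsets of another, representatives are picked
greedily: first the largest set, then at each step the set that grows the
working set the most, until the working set equals the input universe.

All tie-breaks are deterministic and recorded: identical sets keep the
lexicographically smallest representative; greedy ties prefer larger raw
set size, then smaller representative id.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simnet import SimilarityHit

__all__ = [
    "RepresentedSet",
    "RepresentativeSelection",
    "build_represented_sets",
    "select_representatives",
    "representatives_for_clusters",
]


@dataclass(frozen=True)
class RepresentedSet:
    representative_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.representative_id not in self.members:
            raise ValueError("representative must be a member of its own set")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RepresentativeSelection:
    representatives: tuple[str, ...]  # in selection order
    working_set: frozenset[str]
    gains: tuple[int, ...]  # new members contributed at each step


def build_represented_sets(
    hits: list[SimilarityHit],
    universe,
    evalue_max: float = 1e-10,
    coverage_min: float = 0.95,
) -> list[RepresentedSet]:
    """One represented set per query, subset/duplicate sets discarded.

    A subject joins a query's set when the directional hit passes the
    E-value and query-coverage thresholds.  Self-membership is always added
    (a query with no qualifying hits yields a singleton).  Sets that are
    identical to another keep only the lexicographically smallest
    representative id; sets that are proper subsets of another are dropped.
    """
    members: dict[str, set[str]] = {q: {q} for q in universe}
    for h in hits:
        if h.query_id not in members:
            continue
        if h.evalue < evalue_max and h.query_coverage > coverage_min:
            members[h.query_id].add(h.subject_id)

    sets = [RepresentedSet(q, frozenset(m)) for q, m in members.items()]
    # identical sets: keep smallest representative id
    by_members: dict[frozenset, str] = {}
    for rs in sorted(sets, key=lambda r: r.representative_id):
        by_members.setdefault(rs.members, rs.representative_id)
    uniq = [RepresentedSet(rep, mem) for mem, rep in by_members.items()]
    # proper subsets of another set are discarded
    kept = [
        rs for rs in uniq
        if not any(rs.members < other.members for other in uniq)
    ]
    return sorted(kept, key=lambda r: (-len(r.members), r.representative_id))


def select_representatives(
    sets: list[RepresentedSet],
    universe=None,
) -> RepresentativeSelection:
    """Greedy maximum-coverage loop over represented sets.

    At every step the set adding the most new members to the working set is
    chosen (the first step therefore picks the largest set); ties prefer
    the larger raw set, then the lexicographically smaller representative
    id.  Zero-gain candidates are skipped.  Stops when the working set
    covers the universe (the union of all sets unless given explicitly).
    """
    cover: set[str] = set()
    for rs in sets:
        cover |= rs.members
    universe = set(universe) if universe is not None else cover
    uncovered = universe - cover
    if uncovered:
        raise ValueError(
            f"represented sets do not cover the universe; uncovered: {sorted(uncovered)}"
        )

    working: set[str] = set()
    chosen: list[str] = []
    gains: list[int] = []
    remaining = list(sets)
    while working != universe:
        best = None
        best_key = None
        for rs in remaining:
            gain = len(rs.members - working)
            if gain == 0:
                continue
            key = (-gain, -len(rs.members), rs.representative_id)
            if best_key is None or key < best_key:
                best, best_key = rs, key
        assert best is not None  # uncovered nonempty => positive gain exists
        chosen.append(best.representative_id)
        gains.append(len(best.members - working))
        working |= best.members
        remaining.remove(best)
    return RepresentativeSelection(tuple(chosen), frozenset(working), tuple(gains))


def representatives_for_clusters(
    clusters,
    hits: list[SimilarityHit],
    evalue_max: float = 1e-10,
    coverage_min: float = 0.95,
) -> dict[str, RepresentativeSelection]:
    """Run the representative selection independently within each cluster.

    Hits crossing cluster boundaries are ignored (clusters partition the
    node set, so such hits cannot pass the graph thresholds anyway).
    """
    out: dict[str, RepresentativeSelection] = {}
    for cluster in clusters:
        cluster_hits = [
            h for h in hits
            if h.query_id in cluster.members and h.subject_id in cluster.members
        ]
        sets = build_represented_sets(
            cluster_hits, cluster.members, evalue_max, coverage_min
        )
        out[cluster.cluster_id] = select_representatives(sets, cluster.members)
    return out


def write_representatives_tsv(selections: dict[str, RepresentativeSelection], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\trank\trepresentative_id\tgain\n")
        for cid in sorted(selections):
            sel = selections[cid]
            for rank, (rep, gain) in enumerate(zip(sel.representatives, sel.gains)):
                fh.write(f"{cid}\t{rank}\t{rep}\t{gain}\n")
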