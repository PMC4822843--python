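"""Superfamily (clan) assignment from profile-profile relationships.

A family-relationship network is built from reciprocal profile-profile
hits at three tiers of decreasing stringency — "thick" (E < 1e-3),
"thin" (E < 1e-1) and "dotted" (probability score > 90) — the thresholds
conventionally used to delimit clans.  Unassigned families are then folded
into clans by a three-rule cascade, iterated to a fixed point:

1. *threshold*: a thick reciprocal edge to a clan member assigns the clan;
2. *closest-superfamily*: otherwise, if the best clan-labelled hit (by
   probability) belongs to a unique clan, that clan is assigned;
3. *mutual-best-hit*: otherwise, a family that is the mutual best hit of
   an assigned family joins its clan.

Families matching two clans at rule-1 strength are flagged ambiguous and
left unassigned.  The module also provides the UPGMA dendrogram over
profile similarity, Ward-clustered heat-map ordering, and the
subdomain-versus-single-domain comparison for tandem (double) domains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .profiles import ProfileModel, ProfileProfileHit, profile_profile_compare

__all__ = [
    "FamilyGraph",
    "ClanAssignment",
    "build_family_graph",
    "assign_clans",
    "upgma_dendrogram",
    "upgma_newick",
    "subdomain_compare",
    "split_model",
    "family_heatmap",
]

TIERS = ("thick", "thin", "dotted")


@dataclass(frozen=True)
class FamilyGraph:
    nodes: tuple[str, ...]
    # per tier: set of frozenset({a, b}) undirected edges
    thick: frozenset[frozenset]
    thin: frozenset[frozenset]
    dotted: frozenset[frozenset]
    hits: dict  # (a, b) -> ProfileProfileHit, both directions

    def edges(self, tier: str) -> frozenset:
        return getattr(self, tier)

    def neighbors(self, node: str, tier: str) -> set[str]:
        out = set()
        for e in self.edges(tier):
            if node in e:
                out |= set(e) - {node}
        return out


@dataclass(frozen=True)
class ClanAssignment:
    model_id: str
    clan_id: str | None  # None: unassigned or ambiguous
    rule: str  # seed | threshold | closest-superfamily | mutual-best-hit | ambiguous | unassigned
    support: str = ""  # id of the model providing the assignment


def build_family_graph(
    hits: list[ProfileProfileHit],
    node_ids=None,
    e_thick: float = 1e-3,
    e_thin: float = 1e-1,
    prob_dotted: float = 90.0,
) -> FamilyGraph:
    """Reciprocal family network at three independent stringency tiers.

    An edge joins (a, b) at a tier iff the hits in *both* directions pass
    that tier's threshold.  E-value tiers nest (thick implies thin); the
    probability tier is computed independently.
    """
    by_pair: dict[tuple[str, str], ProfileProfileHit] = {}
    nodes = set(node_ids) if node_ids is not None else set()
    for h in hits:
        if h.model_a == h.model_b:
            continue
        by_pair[(h.model_a, h.model_b)] = h
        nodes.add(h.model_a)
        nodes.add(h.model_b)

    thick, thin, dotted = set(), set(), set()
    for (a, b), h in by_pair.items():
        if a > b or (b, a) not in by_pair:
            continue
        back = by_pair[(b, a)]
        pair = frozenset((a, b))
        if h.evalue < e_thick and back.evalue < e_thick:
            thick.add(pair)
        if h.evalue < e_thin and back.evalue < e_thin:
            thin.add(pair)
        if h.probability > prob_dotted and back.probability > prob_dotted:
            dotted.add(pair)
    return FamilyGraph(
        tuple(sorted(nodes)), frozenset(thick), frozenset(thin), frozenset(dotted),
        by_pair,
    )


def assign_clans(
    graph: FamilyGraph,
    seed_clans: dict[str, str],
    max_iterations: int | None = None,
) -> list[ClanAssignment]:
    """Fold unassigned families into clans by the three-rule cascade.

    ``seed_clans`` maps at least one model per known clan.  The cascade
    (threshold > closest-superfamily > mutual-best-hit) is applied to every
    unassigned model each round, and rounds repeat until no assignment
    changes; convergence takes at most one round per model.  A model whose
    thick edges reach two different clans is flagged "ambiguous".
    """
    if not seed_clans:
        raise ValueError("seed_clans must label at least one model")
    assigned: dict[str, ClanAssignment] = {
        m: ClanAssignment(m, c, "seed") for m, c in seed_clans.items()
    }
    frozen_ambiguous: set[str] = set()
    max_iterations = max_iterations or len(graph.nodes) + 1

    for _ in range(max_iterations):
        changed = False
        for node in graph.nodes:
            if node in assigned or node in frozen_ambiguous:
                continue
            # rule 1: thick reciprocal edge to a clan member
            clans = {}
            for nb in graph.neighbors(node, "thick"):
                if nb in assigned and assigned[nb].clan_id:
                    clans.setdefault(assigned[nb].clan_id, nb)
            if len(clans) == 1:
                clan, support = next(iter(clans.items()))
                assigned[node] = ClanAssignment(node, clan, "threshold", support)
                changed = True
                continue
            if len(clans) > 1:
                frozen_ambiguous.add(node)
                changed = True
                continue
            # rule 2: unique closest superfamily by probability
            best: dict[str, tuple[float, str]] = {}
            for (a, b), h in graph.hits.items():
                if a != node or b not in assigned or not assigned[b].clan_id:
                    continue
                clan = assigned[b].clan_id
                if clan not in best or h.probability > best[clan][0]:
                    best[clan] = (h.probability, b)
            if best:
                ranked = sorted(best.items(), key=lambda kv: -kv[1][0])
                if len(ranked) == 1 or ranked[0][1][0] > ranked[1][1][0]:
                    clan, (_, support) = ranked[0]
                    assigned[node] = ClanAssignment(
                        node, clan, "closest-superfamily", support
                    )
                    changed = True
                    continue
            # rule 3: mutual best hit with an assigned model
            mb = _best_hit(graph, node)
            if (
                mb is not None
                and mb in assigned
                and assigned[mb].clan_id
                and _best_hit(graph, mb) == node
            ):
                assigned[node] = ClanAssignment(
                    node, assigned[mb].clan_id, "mutual-best-hit", mb
                )
                changed = True
        if not changed:
            break

    out = []
    for node in graph.nodes:
        if node in assigned:
            out.append(assigned[node])
        elif node in frozen_ambiguous:
            out.append(ClanAssignment(node, None, "ambiguous"))
        else:
            out.append(ClanAssignment(node, None, "unassigned"))
    return out


def _best_hit(graph: FamilyGraph, node: str) -> str | None:
    """Highest-probability directional hit from node (ties: smaller id)."""
    best = None
    for (a, b), h in graph.hits.items():
        if a != node:
            continue
        key = (-h.probability, b)
        if best is None or key < best[0]:
            best = (key, b)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# dendrogram / heat map


def _as_distance(similarity: np.ndarray) -> np.ndarray:
    """100 - probability, symmetrised by the arithmetic mean, zero diagonal."""
    sim = np.asarray(similarity, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    d = 100.0 - (sim + sim.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def upgma_dendrogram(similarity: np.ndarray) -> np.ndarray:
    """UPGMA linkage over a probability-score similarity matrix.

    Distances are ``100 - probability`` (mean-symmetrised).  Returns a
    scipy linkage matrix; merge heights are cophenetic distances, so each
    branch's height above a leaf is half the merge distance (the tree is
    ultrametric).
    """
    d = _as_distance(similarity)
    return sch.average(squareform(d, checks=False))


def upgma_newick(similarity: np.ndarray, labels: list[str]) -> str:
    """Newick string of the UPGMA tree with ultrametric branch lengths."""
    Z = upgma_dendrogram(similarity)
    n = len(labels)
    if n != np.asarray(similarity).shape[0]:
        raise ValueError("labels length must match matrix size")
    # node heights: leaves at 0, internal at merge_distance / 2
    heights = {i: 0.0 for i in range(n)}
    subtree = {i: labels[i] for i in range(n)}
    for k, (ia, ib, dist, _cnt) in enumerate(Z):
        ia, ib = int(ia), int(ib)
        h = dist / 2.0
        node = n + k
        ba = h - heights[ia]
        bb = h - heights[ib]
        subtree[node] = f"({subtree[ia]}:{ba:.12g},{subtree[ib]}:{bb:.12g})"
        heights[node] = h
    return subtree[len(heights) - 1] + ";"


def family_heatmap(
    similarity: np.ndarray,
    labels: list[str],
    prob_floor: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Ward-clustered similarity heat map ordering.

    Probabilities at or below ``prob_floor`` are zeroed; rows are clustered
    by Ward linkage on Euclidean row distances of the floored matrix.
    Returns ``(floored_matrix, linkage, leaf_order_labels)``.
    """
    sim = np.asarray(similarity, dtype=float).copy()
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    sim[sim <= prob_floor] = 0.0
    if np.allclose(sim, sim.flat[0]):
        # degenerate: all values equal (e.g. floor above max) -> input order
        n = sim.shape[0]
        Z = sch.ward(squareform(np.ones((n, n)) - np.eye(n), checks=False))
        return sim, Z, list(labels)
    Z = sch.ward(sim)
    order = sch.leaves_list(sch.optimal_leaf_ordering(Z, sim))
    return sim, Z, [labels[i] for i in order]


# ---------------------------------------------------------------------------
# subdomain comparison


def split_model(model: ProfileModel, split_column: int) -> tuple[ProfileModel, ProfileModel]:
    """Slice a tandem-domain model into N-half and C-half sub-profiles.

    ``split_column`` is the 0-based match-state index starting the C-half;
    it must cut strictly inside the model.
    """
    L = model.length
    if not (0 < split_column < L):
        raise ValueError(f"split column {split_column} outside model of length {L}")

    def slice_model(sl: slice, suffix: str) -> ProfileModel:
        sub = replace(
            model,
            model_id=f"{model.model_id}{suffix}",
            match_emissions=model.match_emissions[sl].copy(),
            tMM=model.tMM[sl].copy(), tMI=model.tMI[sl].copy(),
            tMD=model.tMD[sl].copy(), tIM=model.tIM[sl].copy(),
            tII=model.tII[sl].copy(), tDM=model.tDM[sl].copy(),
            tDD=model.tDD[sl].copy(),
            mu=None, lambda_g=None,
        )
        return sub

    return (
        slice_model(slice(0, split_column), "/N"),
        slice_model(slice(split_column, L), "/C"),
    )


def subdomain_compare(
    double_models: dict[str, ProfileModel],
    split_points: dict[str, int],
    single_models: dict[str, ProfileModel],
    rng_seed: int = 0,
    n_shuffles: int = 100,
) -> list[ProfileProfileHit]:
    """Compare each tandem model's halves against all single-domain models.

    ``split_points`` maps each double model to the 0-based match column
    where its membrane-proximal half starts.  Returns directional hits of
    every half against every single model (and vice versa), from which the
    best-matching single family per half can be read off.
    """
    halves: dict[str, ProfileModel] = {}
    for mid, model in double_models.items():
        if mid not in split_points:
            raise ValueError(f"no split point for model {mid}")
        n_half, c_half = split_model(model, split_points[mid])
        halves[n_half.model_id] = n_half
        halves[c_half.model_id] = c_half

    n_comp = max(1, len(single_models))
    hits = []
    for hid, half in sorted(halves.items()):
        for sid, single in sorted(single_models.items()):
            hits.append(
                profile_profile_compare(
                    half, single, rng_seed=rng_seed, n_shuffles=n_shuffles,
                    n_comparisons=n_comp,
                )
            )
            hits.append(
                profile_profile_compare(
                    single, half, rng_seed=rng_seed, n_shuffles=n_shuffles,
                    n_comparisons=n_comp,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# I/O


def write_family_graph_tsv(graph: FamilyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\ttier\n")
        for tier in TIERS:
            for e in sorted(graph.edges(tier), key=sorted):
                a, b = sorted(e)
                fh.write(f"{a}\t{b}\t{tier}\n")


def write_clans_tsv(assignments: list[ClanAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("model_id\tclan_id\trule\tsupport\n")
        for a in assignments:
            fh.write(f"{a.model_id}\t{a.clan_id or ''}\t{a.rule}\t{a.support}\n")
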