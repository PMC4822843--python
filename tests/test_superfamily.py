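"""Family network tiers, clan-assignment cascade, UPGMA, heat map, subdomains."""

import numpy as np
import pytest

from oracles import naive_upgma
from periscan import synthetic
from periscan.constants import AMINO_ACIDS, SOLUBLE_BACKGROUND
from periscan.profiles import (
    ProfileProfileHit,
    build_profile,
    progressive_align,
)
from periscan.superfamily import (
    assign_clans,
    build_family_graph,
    family_heatmap,
    split_model,
    subdomain_compare,
    upgma_dendrogram,
    upgma_newick,
)


def pp(a, b, e=1.0, prob=0.0):
    return ProfileProfileHit(a, b, 50.0, e, prob, 1, 10, 1, 10, 10)


class TestFamilyGraph:
    def test_strong_reciprocal_pair_is_thick_and_thin(self):
        g = build_family_graph([pp("a", "b", e=1e-5), pp("b", "a", e=1e-5)])
        pair = frozenset(("a", "b"))
        assert pair in g.thick and pair in g.thin and pair not in g.dotted

    def test_one_weak_direction_leaves_only_dotted(self):
        hits = [pp("a", "b", e=1e-4, prob=95.0), pp("b", "a", e=0.5, prob=93.0)]
        g = build_family_graph(hits)
        pair = frozenset(("a", "b"))
        assert pair not in g.thick and pair not in g.thin and pair in g.dotted

    def test_isolated_node_retained(self):
        g = build_family_graph([pp("a", "b", e=1e-5), pp("b", "a", e=1e-5)],
                               node_ids=["a", "b", "z"])
        assert "z" in g.nodes
        assert g.neighbors("z", "thick") == set()

    def test_thick_edges_nest_in_thin(self):
        rng = np.random.default_rng(0)
        hits = []
        names = [f"f{i}" for i in range(6)]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                e1, e2 = 10 ** rng.uniform(-6, 1, size=2)
                hits += [pp(a, b, e=e1), pp(b, a, e=e2)]
        g = build_family_graph(hits)
        assert g.thick <= g.thin


class TestAssignClans:
    def test_threshold_rule(self):
        g = build_family_graph([pp("seed", "x", e=1e-5), pp("x", "seed", e=1e-5)])
        out = {a.model_id: a for a in assign_clans(g, {"seed": "CacheLike"})}
        assert out["x"].clan_id == "CacheLike"
        assert out["x"].rule == "threshold"

    def test_closest_superfamily_rule(self):
        hits = [
            pp("x", "seedA", e=0.5, prob=92.0), pp("seedA", "x", e=0.5, prob=92.0),
            pp("x", "seedB", e=0.5, prob=40.0), pp("seedB", "x", e=0.5, prob=40.0),
        ]
        g = build_family_graph(hits)
        out = {a.model_id: a for a in assign_clans(g, {"seedA": "CA", "seedB": "CB"})}
        assert out["x"].clan_id == "CA"
        assert out["x"].rule == "closest-superfamily"

    def test_mutual_best_hit_rule(self):
        # equal-probability hits into two different clans block rule 2; the
        # orphan and "cb" are mutual best hits, so rule 3 applies
        hits = [
            pp("orphan", "ca", e=0.9, prob=55.0), pp("ca", "orphan", e=0.9, prob=20.0),
            pp("orphan", "cb", e=0.9, prob=55.0), pp("cb", "orphan", e=0.9, prob=55.0),
        ]
        g = build_family_graph(hits)
        out = {
            a.model_id: a
            for a in assign_clans(g, {"ca": "CA", "cb": "CB"})
        }
        # the probability tie breaks to the smaller id ("ca"), whose best
        # hit is the orphan: mutual best pair (orphan, ca)
        assert out["orphan"].clan_id == "CA"
        assert out["orphan"].rule == "mutual-best-hit"

    def test_conflicting_thick_edges_flag_ambiguous(self):
        hits = [
            pp("x", "sa", e=1e-5), pp("sa", "x", e=1e-5),
            pp("x", "sb", e=1e-5), pp("sb", "x", e=1e-5),
        ]
        g = build_family_graph(hits)
        out = {a.model_id: a for a in assign_clans(g, {"sa": "CA", "sb": "CB"})}
        assert out["x"].clan_id is None
        assert out["x"].rule == "ambiguous"

    def test_cascade_reaches_fixed_point_through_chains(self):
        # seed -> x (thick), x -> y (thick): y assigned in a later round
        hits = [
            pp("seed", "x", e=1e-5), pp("x", "seed", e=1e-5),
            pp("x", "y", e=1e-5), pp("y", "x", e=1e-5),
        ]
        g = build_family_graph(hits)
        out = {a.model_id: a for a in assign_clans(g, {"seed": "C"})}
        assert out["y"].clan_id == "C"

    def test_empty_seed_rejected(self):
        g = build_family_graph([pp("a", "b"), pp("b", "a")])
        with pytest.raises(ValueError):
            assign_clans(g, {})


class TestUPGMA:
    def test_three_leaf_hand_computation(self):
        # d(A,B)=2, d(A,C)=d(B,C)=4 as similarities 98/96: ((A:1,B:1):1,C:2)
        sim = np.array([[100.0, 98.0, 96.0], [98.0, 100.0, 96.0], [96.0, 96.0, 100.0]])
        newick = upgma_newick(sim, ["A", "B", "C"])
        assert newick in ("((A:1,B:1):1,C:2);", "(C:2,(A:1,B:1):1);")

    def test_identical_rows_merge_first_at_zero_height(self):
        sim = np.array([[100.0, 100.0, 50.0], [100.0, 100.0, 50.0], [50.0, 50.0, 100.0]])
        Z = upgma_dendrogram(sim)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_ultrametric_root_to_leaf_paths(self):
        rng = np.random.default_rng(4)
        n = 7
        sim = rng.uniform(0, 100, size=(n, n))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 100.0)
        newick = upgma_newick(sim, [f"L{i}" for i in range(n)])
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(newick), "newick")
        depths = tree.depths()
        leaf_depths = [d for cl, d in depths.items() if cl.is_terminal()]
        assert max(leaf_depths) - min(leaf_depths) < 1e-6

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(3, 10))
            sim = rng.uniform(0, 99, size=(n, n))
            sim = (sim + sim.T) / 2
            np.fill_diagonal(sim, 100.0)
            Z = upgma_dendrogram(sim)
            merges = naive_upgma(100.0 - sim)
            # compare the merge heights multiset and member partitions
            got = sorted(round(z / 2.0, 9) for z in Z[:, 2])
            want = sorted(round(h, 9) for _, h in merges)
            assert got == pytest.approx(want)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            upgma_dendrogram(np.ones((2, 3)))


class TestHeatmap:
    def test_block_structure_groups_contiguously(self):
        blocks = [0, 0, 1, 1, 2, 2]
        n = len(blocks)
        sim = np.full((n, n), 10.0)
        for i in range(n):
            for j in range(n):
                if blocks[i] == blocks[j]:
                    sim[i, j] = 95.0
        labels = [f"m{i}" for i in range(n)]
        _, _, order = family_heatmap(sim, labels)
        order_blocks = [blocks[labels.index(x)] for x in order]
        # members of each block must be adjacent in leaf order
        for b in set(blocks):
            pos = [i for i, ob in enumerate(order_blocks) if ob == b]
            assert max(pos) - min(pos) == len(pos) - 1

    def test_floor_above_max_gives_flat_input_order(self):
        sim = np.full((4, 4), 15.0)
        floored, _, order = family_heatmap(sim, list("abcd"), prob_floor=20.0)
        assert np.all(floored == 0.0)
        assert order == list("abcd")

    def test_row_permutation_invariance_of_partitions(self):
        blocks = [0, 0, 1, 1]
        sim = np.array(
            [[95, 95, 10, 10], [95, 95, 10, 10], [10, 10, 95, 95], [10, 10, 95, 95]],
            dtype=float,
        )
        labels = list("abcd")
        _, _, order1 = family_heatmap(sim, labels)
        perm = [2, 0, 3, 1]
        sim2 = sim[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        _, _, order2 = family_heatmap(sim2, labels2)
        groups1 = {frozenset(order1[:2]), frozenset(order1[2:])}
        groups2 = {frozenset(order2[:2]), frozenset(order2[2:])}
        assert groups1 == groups2


class TestSubdomains:
    def build_family(self, cons, mid, seed):
        members = {
            f"{mid}_{i}": synthetic.sample_family_member(cons, 0.25, seed + i)
            for i in range(10)
        }
        return build_profile(progressive_align(members), model_id=mid)

    def test_fusion_halves_match_their_sources(self):
        """The tandem's N-half best-matches its N-source family, C-half its C-source."""
        rng = np.random.default_rng(71)

        def rand_cons(n):
            return "".join(
                AMINO_ACIDS[i] for i in rng.choice(20, size=n, p=SOLUBLE_BACKGROUND)
            )

        s2 = synthetic.FamilyConsensus("S2", rand_cons(110), "single")
        s3 = synthetic.FamilyConsensus("S3", rand_cons(110), "single")
        s4 = synthetic.FamilyConsensus("S4", rand_cons(110), "single")
        fused = synthetic.fuse_consensi("DBL", s3, s2)

        singles = {
            c.family_id: self.build_family(c.sequence, c.family_id, seed)
            for c, seed in ((s2, 100), (s3, 200), (s4, 300))
        }
        double_model = self.build_family(fused.sequence, "DBL", 400)
        # split at the match column nearest the recorded fusion boundary
        split = round(double_model.length * fused.subdomain_boundary / len(fused.sequence))
        hits = subdomain_compare(
            {"DBL": double_model}, {"DBL": split}, singles, rng_seed=5
        )
        best = {}
        for h in hits:
            if h.model_a.startswith("DBL/"):
                half = h.model_a.split("/")[1]
                if half not in best or h.probability > best[half][1]:
                    best[half] = (h.model_b, h.probability)
        assert best["N"][0] == "S3"
        assert best["C"][0] == "S2"

    def test_split_at_zero_rejected(self):
        model = self.build_family("ACDEFGHIKL" * 8, "m", 1)
        with pytest.raises(ValueError):
            split_model(model, 0)
        with pytest.raises(ValueError):
            split_model(model, model.length)

    def test_half_self_comparison_ranks_first(self):
        model = self.build_family("ACDEFGHIKLMNPQRSTVWY" * 5, "m", 7)
        n_half, _ = split_model(model, model.length // 2)
        others = {
            "o1": self.build_family("WYVTSRQPNMLKIHGFEDCA" * 5, "o1", 11),
            "n_half_copy": n_half,
        }
        from periscan.profiles import profile_profile_compare

        self_hit = profile_profile_compare(n_half, n_half, rng_seed=2)
        other_hit = profile_profile_compare(n_half, others["o1"], rng_seed=2)
        assert self_hit.probability >= other_hit.probability
        assert self_hit.score > other_hit.score
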