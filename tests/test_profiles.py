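"""Profile construction, forward scoring, calibration, scanning, comparison."""

import math

import numpy as np
import pytest

from oracles import enumerate_forward
from conftest import random_toy_model
from periscan import synthetic
from periscan.constants import AMINO_ACIDS, BACKGROUND, SOLUBLE_BACKGROUND
from periscan.profiles import (
    Alignment,
    build_profile,
    calibrate,
    fit_gumbel,
    forward_score,
    merge_clusters,
    model_from_json,
    model_to_json,
    profile_profile_compare,
    progressive_align,
    scan,
    score_pvalue,
    viterbi_envelope,
)


class TestProgressiveAlign:
    def test_identical_pair_gapfree(self):
        aln = progressive_align({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL"})
        assert aln.rows == ("ACDEFGHIKL", "ACDEFGHIKL")

    def test_single_gap_for_single_deletion(self):
        aln = progressive_align({"a": "ACDE", "b": "ACE"})
        rows = dict(zip(aln.ids, aln.rows))
        assert rows["a"] == "ACDE"
        assert rows["b"].replace("-", "") == "ACE"
        assert rows["b"].count("-") == 1

    def test_width_at_least_longest_sequence(self):
        seqs = {"a": "ACDEFGHIKLMNP", "b": "ACDFGHIKL", "c": "CDEFGHIK"}
        aln = progressive_align(seqs)
        assert aln.width >= 13
        for i, row in zip(aln.ids, aln.rows):
            assert row.replace("-", "") == seqs[i]

    def test_single_sequence_trivial(self):
        aln = progressive_align({"only": "ACD"})
        assert aln.rows == ("ACD",)


class TestBuildProfile:
    def test_single_sequence_near_zero_pseudocount(self):
        aln = Alignment(("s",), ("AAA",))
        model = build_profile(aln, pseudocount_weight=1e-9)
        assert model.length == 3
        a = AMINO_ACIDS.index("A")
        assert np.all(model.match_emissions[:, a] > 0.999)

    def test_all_gap_column_not_a_match_state(self):
        aln = Alignment(("s1", "s2"), ("A-C", "A-C"))
        model = build_profile(aln)
        assert model.length == 2

    def test_half_occupied_column_is_match_at_default_fraction(self):
        # >= rule: exactly 50% occupancy still becomes a match state
        aln = Alignment(("s1", "s2"), ("AC", "A-"))
        model = build_profile(aln, match_fraction=0.5)
        assert model.length == 2

    def test_zero_match_columns_rejected(self):
        aln = Alignment(("s1", "s2", "s3"), ("A--", "-C-", "--D"))
        with pytest.raises(ValueError):
            build_profile(aln, match_fraction=0.5)

    def test_distributions_normalised(self):
        recs = {f"m{i}": synthetic.sample_family_member("ACDEFGHIKLMNPQRSTVWY" * 4, 0.3, i)
                for i in range(6)}
        model = build_profile(progressive_align(recs))
        model.validate()  # asserts normalisation internally


class TestForwardScore:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            L = int(rng.integers(1, 4))
            model = random_toy_model(rng, L, f"m{trial}")
            n = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
            got = forward_score(model, seq)
            want = enumerate_forward(model, seq)
            assert got == pytest.approx(want, rel=1e-9)

    def test_empty_sequence_defined(self):
        rng = np.random.default_rng(1)
        model = random_toy_model(rng, 2, "m")
        assert forward_score(model, "") == -math.inf

    def test_consensus_outscores_every_point_mutant(self):
        consensus = "WCHKMFPDE"
        model = build_profile(Alignment(("c",), (consensus,)), pseudocount_weight=0.1)
        base = forward_score(model, consensus)
        for i in range(len(consensus)):
            for aa in AMINO_ACIDS:
                if aa == consensus[i]:
                    continue
                mutant = consensus[:i] + aa + consensus[i + 1 :]
                assert forward_score(model, mutant) <= base

    def test_null_emission_model_scores_near_zero_on_background(self):
        # a model whose match states emit the background has odds 1 per
        # residue; over random background sequences the mean score is ~0
        L = 4
        em = np.tile(BACKGROUND, (L, 1))
        rng = np.random.default_rng(2)
        model = random_toy_model(rng, L, "null")
        from dataclasses import replace

        model = replace(model, match_emissions=em)
        scores = []
        for i in range(1000):
            idx = rng.choice(len(AMINO_ACIDS), size=100, p=BACKGROUND)
            seq = "".join(AMINO_ACIDS[j] for j in idx)
            scores.append(forward_score(model, seq))
        assert abs(float(np.mean(scores))) <= 0.5


class TestCalibration:
    def make_calibrated(self, seed=0):
        recs = {f"m{i}": synthetic.sample_family_member("ACDEFGHIKLMNPQRSTVWY" * 5, 0.25, i)
                for i in range(8)}
        model = build_profile(progressive_align(recs), model_id="fam")
        return calibrate(model, n_random=300, random_length=150, rng_seed=seed)

    def test_pvalue_at_mu_is_gumbel_closed_form(self):
        model = self.make_calibrated()
        assert score_pvalue(model, model.mu) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_evalue_monotone_decreasing(self):
        model = self.make_calibrated()
        ps = [score_pvalue(model, s) for s in np.linspace(model.mu - 5, model.mu + 30, 10)]
        assert ps == sorted(ps, reverse=True)

    def test_gumbel_parameter_recovery(self):
        # frozen draws from a known Gumbel(mu=10, lambda=0.7)
        from scipy.stats import gumbel_r

        draws = gumbel_r.rvs(loc=10.0, scale=1 / 0.7, size=5000,
                             random_state=np.random.default_rng(42))
        mu, lam = fit_gumbel(draws)
        assert mu == pytest.approx(10.0, rel=0.05)
        assert lam == pytest.approx(0.7, rel=0.05)

    def test_too_few_random_sequences_rejected(self):
        recs = {f"m{i}": synthetic.sample_family_member("ACDEF" * 10, 0.25, i)
                for i in range(4)}
        model = build_profile(progressive_align(recs))
        with pytest.raises(ValueError):
            calibrate(model, n_random=50)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_gumbel(np.ones(500))


class TestScan:
    def build_family_model(self, consensus, n=12, seed=0, divergence=0.25):
        members = {
            f"m{i}": synthetic.sample_family_member(consensus, divergence, seed * 100 + i)
            for i in range(n)
        }
        model = build_profile(progressive_align(members), model_id="fam")
        return calibrate(model, 300, 200, rng_seed=seed, composition=SOLUBLE_BACKGROUND)

    def test_planted_member_detected(self):
        rng = np.random.default_rng(7)
        cons = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=120, p=SOLUBLE_BACKGROUND)
        )
        model = self.build_family_model(cons, seed=3)
        member = synthetic.sample_family_member(cons, 0.25, 999)
        hits = scan([model], {"p": member}, 1e-3, 1e-3)
        assert len(hits) >= 1
        assert hits[0].dom_evalue < 1e-3

    def test_tandem_domains_give_two_envelopes(self):
        rng = np.random.default_rng(8)
        cons = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=100, p=SOLUBLE_BACKGROUND)
        )
        model = self.build_family_model(cons, seed=4)
        d1 = synthetic.sample_family_member(cons, 0.25, 555)
        d2 = synthetic.sample_family_member(cons, 0.25, 556)
        linker = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=30, p=SOLUBLE_BACKGROUND)
        )
        protein = linker + d1 + linker + d2 + linker
        hits = scan([model], {"p": protein}, 1e-3, 1e-3)
        assert len(hits) >= 2
        h1, h2 = sorted(hits, key=lambda h: h.start)[:2]
        assert h1.end < h2.start  # non-overlapping envelopes

    def test_uncalibrated_model_rejected(self):
        model = build_profile(Alignment(("s",), ("ACDEFGHIKL",)))
        with pytest.raises(ValueError):
            scan([model], {"p": "ACDEFGHIKL"})

    def test_viterbi_envelope_covers_planted_domain(self):
        rng = np.random.default_rng(9)
        cons = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=100, p=SOLUBLE_BACKGROUND)
        )
        model = self.build_family_model(cons, seed=5)
        flank = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=40, p=SOLUBLE_BACKGROUND)
        )
        member = synthetic.sample_family_member(cons, 0.25, 777)
        protein = flank + member + flank
        _, s, e = viterbi_envelope(model, protein)
        assert abs(s - 41) <= 10 and abs(e - (40 + len(member))) <= 10


class TestProfileProfile:
    def family_model(self, seed, length=100, divergence=0.25, mid=None):
        rng = np.random.default_rng(seed)
        cons = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=SOLUBLE_BACKGROUND)
        )
        members = {
            f"m{i}": synthetic.sample_family_member(cons, divergence, seed * 1000 + i)
            for i in range(10)
        }
        return build_profile(progressive_align(members), model_id=mid or f"fam{seed}"), cons

    def test_self_comparison_is_maximal(self):
        models = [self.family_model(s)[0] for s in (1, 2, 3)]
        a = models[0]
        self_hit = profile_profile_compare(a, a, rng_seed=0)
        for other in models[1:]:
            cross = profile_profile_compare(a, other, rng_seed=0)
            assert self_hit.probability >= cross.probability
            assert self_hit.score > cross.score

    def test_unrelated_models_are_insignificant(self):
        # E-values count expected false positives over the experiment's
        # comparisons (here 20 null pairs), as in the pipeline's library scans
        ok = 0
        trials = 20
        for t in range(trials):
            a, _ = self.family_model(100 + t)
            b, _ = self.family_model(200 + t)
            h = profile_profile_compare(a, b, rng_seed=t, n_comparisons=trials)
            if h.evalue >= 0.1:
                ok += 1
        assert ok / trials >= 0.95

    def test_two_halves_of_one_family_are_confidently_related(self):
        rng = np.random.default_rng(33)
        cons = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=100, p=SOLUBLE_BACKGROUND)
        )
        half_a = {
            f"a{i}": synthetic.sample_family_member(cons, 0.25, 4000 + i) for i in range(10)
        }
        half_b = {
            f"b{i}": synthetic.sample_family_member(cons, 0.25, 5000 + i) for i in range(10)
        }
        ma = build_profile(progressive_align(half_a), model_id="halfA")
        mb = build_profile(progressive_align(half_b), model_id="halfB")
        h = profile_profile_compare(ma, mb, rng_seed=1)
        assert h.probability > 90

    def test_score_symmetry(self):
        a, _ = self.family_model(11)
        b, _ = self.family_model(12)
        ab = profile_profile_compare(a, b, rng_seed=5)
        ba = profile_profile_compare(b, a, rng_seed=5)
        assert ab.score == pytest.approx(ba.score, abs=1e-9)

    def test_zero_length_model_rejected(self):
        a, _ = self.family_model(13)
        from dataclasses import replace

        broken = replace(a, match_emissions=a.match_emissions[:0])
        with pytest.raises(ValueError):
            profile_profile_compare(a, broken)


class TestMergeClusters:
    def split_family_fixture(self):
        rng = np.random.default_rng(44)
        cons = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=110, p=SOLUBLE_BACKGROUND)
        )
        rng2 = np.random.default_rng(55)
        other = "".join(
            AMINO_ACIDS[i] for i in rng2.choice(20, size=110, p=SOLUBLE_BACKGROUND)
        )
        aligns = {}
        for name, source, base in (("c1", cons, 0), ("c2", cons, 100), ("c3", other, 200)):
            members = {
                f"{name}_{i}": synthetic.sample_family_member(source, 0.25, base + i)
                for i in range(8)
            }
            aligns[name] = progressive_align(members)
        models = {k: build_profile(a, model_id=k) for k, a in aligns.items()}
        return aligns, models

    def test_same_family_fragments_merge_unrelated_do_not(self):
        aligns, models = self.split_family_fixture()
        merged_aligns, merged_models = merge_clusters(aligns, models, rng_seed=6)
        assert set(merged_models) == {"c1+c2", "c3"}
        assert len(merged_aligns["c1+c2"]) == 16

    def test_merge_is_order_independent(self):
        aligns, models = self.split_family_fixture()
        a1, m1 = merge_clusters(aligns, models, rng_seed=6)
        rev_aligns = dict(reversed(list(aligns.items())))
        rev_models = dict(reversed(list(models.items())))
        a2, m2 = merge_clusters(rev_aligns, rev_models, rng_seed=6)
        assert set(m1) == set(m2)


class TestModelSerialisation:
    def test_json_roundtrip_preserves_probabilities(self):
        rng = np.random.default_rng(21)
        model = random_toy_model(rng, 3, "toy")
        model = calibrate(model, 300, 60, rng_seed=1)
        back = model_from_json(model_to_json(model))
        np.testing.assert_allclose(back.match_emissions, model.match_emissions, atol=1e-12)
        np.testing.assert_allclose(back.tMM, model.tMM, atol=1e-12)
        assert back.mu == pytest.approx(model.mu)
        assert back.lambda_g == pytest.approx(model.lambda_g)

    def test_missing_field_rejected(self):
        import json

        rng = np.random.default_rng(22)
        payload = json.loads(model_to_json(random_toy_model(rng, 2, "toy")))
        del payload["transitions"]
        with pytest.raises(ValueError, match="transitions"):
            model_from_json(json.dumps(payload))
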