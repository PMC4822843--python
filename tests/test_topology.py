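"""Topology prediction and region extraction: exact filters, recoverability."""

import pytest

from periscan import synthetic, topology
from periscan.profiles import DomainHit
from periscan.topology import (
    ExtracellularRegion,
    Segment,
    TopologyAnnotation,
    classify_localization,
    extract_regions,
    filter_sensor_context,
    localization_fractions,
    predict_topology,
)


def ann(pid, *segs):
    return TopologyAnnotation(pid, tuple(Segment(*s) for s in segs))


class TestPredictTopology:
    def test_all_glycine_has_no_membrane(self):
        a = predict_topology("p", "G" * 100)
        assert all(s.label != "membrane" for s in a.segments)

    def test_window_longer_than_sequence_is_single_loop(self):
        a = predict_topology("p", "ACDEFGHIKL", window=19)
        assert len(a.segments) == 1
        assert a.segments[0] == Segment("inside", 1, 10)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            predict_topology("p", "")

    def test_segments_tile_and_alternate(self):
        recs, _, _ = synthetic.generate_proteome(
            synthetic.default_architecture(40), synthetic.default_families(),
            n_taxa=4, rng_seed=5,
        )
        for rec in recs:
            a = predict_topology(rec.protein_id, rec.sequence)
            a.validate(len(rec.sequence))  # tiling + no adjacent membranes

    def test_planted_tm_segments_overlap_predictions(self):
        """Both planted TM helices are recovered with Jaccard >= 0.5."""
        recs, truth, _ = synthetic.generate_proteome(
            synthetic.default_architecture(80), synthetic.default_families(),
            n_taxa=4, rng_seed=5,
        )
        truth_by = {t.protein_id: t for t in truth}
        ok = total = 0
        for rec in recs:
            t = truth_by[rec.protein_id]
            if t.cls != "sensor-bearing":
                continue
            true_tms = [
                (s.start, s.end)
                for s in topology.parse_topology_string(rec.protein_id, t.topology).segments
                if s.label == "membrane"
            ]
            pred = predict_topology(rec.protein_id, rec.sequence)
            pred_tms = [(s.start, s.end) for s in pred.segments if s.label == "membrane"]
            for ts, te in true_tms:
                total += 1
                for ps, pe in pred_tms:
                    inter = max(0, min(te, pe) - max(ts, ps) + 1)
                    union = (te - ts + 1) + (pe - ps + 1) - inter
                    if inter / union >= 0.5:
                        ok += 1
                        break
        assert ok / total >= 0.95


class TestExtractRegions:
    SEQ = "A" * 200

    def test_basic_flanked_region(self):
        a = ann("p", ("inside", 1, 10), ("membrane", 11, 30), ("outside", 31, 100),
                ("membrane", 101, 120), ("inside", 121, 200))
        regions = extract_regions(a, self.SEQ)
        assert [(r.start, r.end, r.length) for r in regions] == [(31, 100, 70)]

    def test_length_exactly_fifty_rejected_fifty_one_kept(self):
        # strict "longer than 50": 50 fails, 51 passes
        a50 = ann("p", ("inside", 1, 10), ("membrane", 11, 30), ("outside", 31, 80),
                  ("membrane", 81, 100), ("inside", 101, 200))
        assert extract_regions(a50, self.SEQ) == []
        a51 = ann("p", ("inside", 1, 10), ("membrane", 11, 30), ("outside", 31, 81),
                  ("membrane", 82, 101), ("inside", 102, 200))
        out = extract_regions(a51, self.SEQ)
        assert len(out) == 1 and out[0].length == 51

    def test_terminal_outside_segment_not_returned(self):
        # an N-terminal outside loop precedes the first TM: not flanked
        a = ann("p", ("outside", 1, 80), ("membrane", 81, 100), ("inside", 101, 200))
        assert extract_regions(a, self.SEQ) == []

    def test_regions_in_n_to_c_order_and_idempotent(self):
        a = ann("p", ("inside", 1, 5), ("membrane", 6, 25), ("outside", 26, 90),
                ("membrane", 91, 110), ("inside", 111, 115), ("membrane", 116, 135),
                ("outside", 136, 195), ("membrane", 196, 198), ("inside", 199, 200))
        r1 = extract_regions(a, self.SEQ)
        r2 = extract_regions(a, self.SEQ)
        assert r1 == r2
        assert [r.start for r in r1] == sorted(r.start for r in r1)
        assert [r.tm_pair_index for r in r1] == [0, 1]

    def test_region_recovery_on_seeded_proteome(self):
        """>=95% of planted regions recovered within +/-5 residues a side."""
        recs, truth, _ = synthetic.generate_proteome(
            synthetic.default_architecture(), synthetic.default_families(),
            n_taxa=8, rng_seed=1,
        )
        truth_by = {t.protein_id: t for t in truth}
        hit = tot = 0
        for rec in recs:
            t = truth_by[rec.protein_id]
            if t.cls != "sensor-bearing":
                continue
            tot += 1
            regs = extract_regions(
                predict_topology(rec.protein_id, rec.sequence), rec.sequence
            )
            if any(
                abs(r.start - t.region_start) <= 5 and abs(r.end - t.region_end) <= 5
                for r in regs
            ):
                hit += 1
        assert hit / tot >= 0.95


class TestSensorContextFilter:
    REGION = ExtracellularRegion("p1", 31, 100, "A" * 70, 0)

    def hit(self, pid, start, end):
        return DomainHit(pid, "out_model", start, end, 50.0, 1e-9, 1e-9)

    def test_region_kept_when_output_hit_elsewhere(self):
        kept = filter_sensor_context([self.REGION], [self.hit("p1", 150, 200)])
        assert kept == [self.REGION]

    def test_region_dropped_without_output_hit(self):
        assert filter_sensor_context([self.REGION], []) == []
        assert filter_sensor_context([self.REGION], [self.hit("p2", 150, 200)]) == []

    def test_hit_overlapping_region_does_not_count(self):
        # the output domain must be a separate module, not the region itself
        assert filter_sensor_context([self.REGION], [self.hit("p1", 60, 90)]) == []
        kept = filter_sensor_context(
            [self.REGION], [self.hit("p1", 60, 90), self.hit("p1", 150, 200)]
        )
        assert kept == [self.REGION]


class TestLocalization:
    def make_ann(self):
        return {
            "p1": ann("p1", ("inside", 1, 10), ("membrane", 11, 30),
                      ("outside", 31, 100), ("membrane", 101, 120), ("inside", 121, 200)),
            "p2": ann("p2", ("inside", 1, 200)),
        }

    def test_hit_inside_outside_segment_is_extracellular(self):
        df = classify_localization(
            [DomainHit("p1", "m", 40, 90, 10, 1e-5, 1e-5)], self.make_ann()
        )
        assert df.localization.tolist() == ["extracellular"]

    def test_hit_on_tm_less_protein_is_intracellular(self):
        df = classify_localization(
            [DomainHit("p2", "m", 40, 90, 10, 1e-5, 1e-5)], self.make_ann()
        )
        assert df.localization.tolist() == ["intracellular"]

    def test_unannotated_protein_is_unknown(self):
        df = classify_localization(
            [DomainHit("p9", "m", 40, 90, 10, 1e-5, 1e-5)], self.make_ann()
        )
        assert df.localization.tolist() == ["unknown"]

    def test_per_family_fractions(self):
        hits = [DomainHit("p1", "m", 40, 90, 10, 1e-5, 1e-5)] * 8 + [
            DomainHit("p2", "m", 40, 90, 10, 1e-5, 1e-5)
        ] * 2
        df = classify_localization(hits, self.make_ann())
        frac = localization_fractions(df)
        assert frac.loc["m", "extracellular"] == pytest.approx(0.8)
        assert frac.loc["m", "intracellular"] == pytest.approx(0.2)


class TestTopologyIO:
    def test_tsv_roundtrip(self, tmp_path):
        a = ann("p1", ("inside", 1, 10), ("membrane", 11, 30), ("outside", 31, 60))
        p = tmp_path / "topo.tsv"
        topology.write_topology_tsv([a], p)
        back = topology.read_topology_tsv(p)
        assert back["p1"] == a

    def test_region_fasta_roundtrip(self, tmp_path):
        r = ExtracellularRegion("prot7", 31, 100, "ACDEFGHIKL" * 7, 0)
        p = tmp_path / "regions.fasta"
        topology.write_regions_fasta([r], p)
        back = topology.read_regions_fasta(p)
        assert back[0].protein_id == "prot7"
        assert (back[0].start, back[0].end) == (31, 100)
        assert back[0].sequence == r.sequence
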