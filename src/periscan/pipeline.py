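"""End-to-end pipeline driver on the synthetic benchmark proteome.

Stage order mirrors the model-construction flow the package implements:

    simulate -> topology -> extract -> reduce -> network -> cluster ->
    represent -> align -> build/calibrate -> merge -> scan -> clans -> census

Each stage checkpoints its outputs (with SHA-256 checksums) into a run
manifest; re-running in the same directory skips stages whose outputs are
intact and whose configuration is unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import census as census_mod
from . import profiles, repselect, simnet, superfamily, synthetic, topology
from .config import PipelineConfig
from .constants import SOLUBLE_BACKGROUND

log = logging.getLogger("periscan")

__all__ = ["run_pipeline", "RunManifest", "PipelineState"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    """Stage completion records with output checksums."""

    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_fresh(self, name: str, outputs: list[Path], config_hash: str) -> bool:
        rec = self.data["stages"].get(name)
        if not rec or rec.get("config_hash") != config_hash:
            return False
        for p in outputs:
            if not p.exists() or rec["outputs"].get(p.name) != _sha256(p):
                return False
        return True

    def record(self, name: str, outputs: list[Path], config_hash: str, seconds: float) -> None:
        self.data["stages"][name] = {
            "status": "ok",
            "config_hash": config_hash,
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(seconds, 2),
            "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


@dataclasses.dataclass
class PipelineState:
    """In-memory artifacts shared between stages."""

    records: list = None
    truth: list = None
    meta: dict = None
    annotations: dict = None
    regions: list = None
    retained: dict = None
    hits: list = None
    graph: object = None
    clusters: list = None
    filtered: list = None
    selections: dict = None
    alignments: dict = None
    models: dict = None
    output_model: object = None
    domain_hits: list = None
    pp_hits: list = None
    family_graph: object = None
    clan_assignments: list = None
    cluster_family: dict = None
    results: dict = dataclasses.field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    families: list[synthetic.FamilySpec] | None = None,
) -> RunManifest:
    """Execute all stages; returns the completed manifest.

    ``families`` defaults to the six-family two-superfamily benchmark set.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(outdir / "manifest.json")
    cfg_hash = hashlib.sha256(config.to_json().encode()).hexdigest()[:16]
    (outdir / "config.json").write_text(config.to_json())
    fams = families or synthetic.default_families()
    state = PipelineState()

    def stage(name, outputs, compute, load):
        paths = [outdir / o for o in outputs]
        t0 = time.time()
        if manifest.stage_fresh(name, paths, cfg_hash):
            log.info("stage %s: up to date, skipping", name)
            load(paths)
            return
        log.info("stage %s: running", name)
        try:
            compute(paths)
        except StageFailure:
            raise
        except Exception as exc:  # halt with the stage name
            raise StageFailure(name, str(exc)) from exc
        manifest.record(name, paths, cfg_hash, time.time() - t0)
        log.info("stage %s: done in %.1fs", name, time.time() - t0)

    # ---------------------------------------------------------------- simulate
    def sim_compute(paths):
        recs, truth, meta = synthetic.generate_proteome(
            synthetic.default_architecture(config.n_proteins), fams,
            n_taxa=config.n_taxa, rng_seed=config.rng_seed,
            ancestor_divergence=config.ancestor_divergence,
            anchor_fraction=config.anchor_fraction,
        )
        synthetic.write_fasta(recs, paths[0])
        synthetic.write_truth_table(truth, paths[1])
        synthetic.write_meta(meta, paths[2])
        state.records, state.truth, state.meta = recs, truth, meta

    def sim_load(paths):
        state.truth = synthetic.read_truth_table(paths[1])
        state.meta = json.loads(paths[2].read_text())
        state.records = _read_fasta_records(paths[0])

    stage("simulate", ["proteome.fasta", "truth.tsv", "params.json"], sim_compute, sim_load)

    # ---------------------------------------------------------------- topology
    def topo_compute(paths):
        anns = {
            rec.protein_id: topology.predict_topology(
                rec.protein_id, rec.sequence,
                window=config.hydropathy_window,
                threshold=config.hydropathy_threshold,
                min_tm_run=config.min_tm_run,
                n_terminus=config.n_terminus,
            )
            for rec in state.records
        }
        topology.write_topology_tsv(anns.values(), paths[0])
        state.annotations = anns

    def topo_load(paths):
        state.annotations = topology.read_topology_tsv(paths[0])

    stage("topology", ["topology.tsv"], topo_compute, topo_load)

    # ----------------------------------------------------------------- extract
    def extract_compute(paths):
        seq_of = {r.protein_id: r.sequence for r in state.records}
        regions = []
        for pid in sorted(state.annotations):
            regions += topology.extract_regions(
                state.annotations[pid], seq_of[pid], config.min_region_length
            )
        # sensor-context filter: an output-domain hit elsewhere on the protein
        motif = synthetic.DEFAULT_OUTPUT_MOTIF
        out_model = profiles.build_profile(
            profiles.Alignment(("output",), (motif,)), model_id="output_domain",
        )
        out_model = profiles.calibrate(
            out_model, config.calibration_n, config.calibration_length,
            rng_seed=config.rng_seed + 1, composition=SOLUBLE_BACKGROUND,
        )
        output_hits = profiles.scan(
            [out_model], seq_of,
            config.scan_seq_evalue_max, config.scan_dom_evalue_max,
        )
        regions = topology.filter_sensor_context(regions, output_hits)
        topology.write_regions_fasta(regions, paths[0])
        state.regions = regions
        state.output_model = out_model

    def extract_load(paths):
        state.regions = topology.read_regions_fasta(paths[0])

    stage("extract", ["regions.fasta"], extract_compute, extract_load)

    # ------------------------------------------------------------------ reduce
    def reduce_compute(paths):
        seqs = {r.region_id: r.sequence for r in state.regions}
        retained = simnet.reduce_redundancy(seqs, config.redundancy_identity)
        (paths[0]).write_text("\n".join(retained) + "\n")
        state.retained = {k: seqs[k] for k in retained}

    def reduce_load(paths):
        ids = paths[0].read_text().split()
        seqs = {r.region_id: r.sequence for r in state.regions}
        state.retained = {k: seqs[k] for k in ids}

    stage("reduce", ["retained.txt"], reduce_compute, reduce_load)

    # ----------------------------------------------------------------- network
    def net_compute(paths):
        hits = simnet.all_vs_all(state.retained)
        simnet.write_hits_tsv(hits, paths[0])
        state.hits = hits

    def net_load(paths):
        state.hits = simnet.read_hits_tsv(paths[0])

    stage("network", ["hits.tsv"], net_compute, net_load)

    # ----------------------------------------------------------------- cluster
    def cluster_compute(paths):
        graph = simnet.build_graph(
            state.hits, state.retained.keys(),
            config.graph_evalue_max, config.graph_coverage_min,
        )
        allc, filt = simnet.components(graph, config.cluster_min_size)
        simnet.write_clusters_tsv(allc, paths[0])
        simnet.write_edges_tsv(graph, paths[1])
        state.graph, state.clusters, state.filtered = graph, allc, filt

    def cluster_load(paths):
        graph = simnet.build_graph(
            state.hits, state.retained.keys(),
            config.graph_evalue_max, config.graph_coverage_min,
        )
        allc, filt = simnet.components(graph, config.cluster_min_size)
        state.graph, state.clusters, state.filtered = graph, allc, filt

    stage("cluster", ["clusters.tsv", "edges.tsv"], cluster_compute, cluster_load)

    # --------------------------------------------------------------- represent
    def rep_compute(paths):
        sels = repselect.representatives_for_clusters(
            state.filtered, state.hits,
            config.represent_evalue_max, config.represent_coverage_min,
        )
        repselect.write_representatives_tsv(sels, paths[0])
        state.selections = sels

    def rep_load(paths):
        rep_compute(paths)

    stage("represent", ["representatives.tsv"], rep_compute, rep_load)

    # ------------------------------------------------- align + build/calibrate
    def build_compute(paths):
        aligns = {}
        models = {}
        for c in state.filtered:
            aln = profiles.progressive_align(
                {m: state.retained[m] for m in sorted(c.members)}
            )
            aligns[c.cluster_id] = aln
            model = profiles.build_profile(
                aln, model_id=c.cluster_id,
                match_fraction=config.match_fraction,
                pseudocount_weight=config.pseudocount_weight,
            )
            models[c.cluster_id] = profiles.calibrate(
                model, config.calibration_n, config.calibration_length,
                rng_seed=config.rng_seed + 2, composition=SOLUBLE_BACKGROUND,
            )
        _write_models(models, paths[0])
        _write_alignments(aligns, paths[1])
        state.alignments, state.models = aligns, models

    def build_load(paths):
        state.models = _read_models(paths[0])
        state.alignments = _read_alignments(paths[1])

    stage("build", ["models.json", "alignments.json"], build_compute, build_load)

    # ------------------------------------------------------------------- merge
    def merge_compute(paths):
        aligns, models = profiles.merge_clusters(
            state.alignments, state.models,
            probability_min=config.merge_probability_min,
            coverage_min=config.merge_coverage_min,
            min_bits_per_column=config.merge_min_bits_per_column,
            rng_seed=config.rng_seed + 3,
            n_shuffles=config.pp_shuffles,
            match_fraction=config.match_fraction,
            pseudocount_weight=config.pseudocount_weight,
        )
        models = {
            mid: (
                m if m.calibrated else profiles.calibrate(
                    m, config.calibration_n, config.calibration_length,
                    rng_seed=config.rng_seed + 4, composition=SOLUBLE_BACKGROUND,
                )
            )
            for mid, m in models.items()
        }
        _write_models(models, paths[0])
        _write_alignments(aligns, paths[1])
        state.alignments, state.models = aligns, models

    def merge_load(paths):
        state.models = _read_models(paths[0])
        state.alignments = _read_alignments(paths[1])

    stage("merge", ["models_merged.json", "alignments_merged.json"], merge_compute, merge_load)

    # -------------------------------------------------------------------- scan
    def scan_compute(paths):
        seq_of = {r.protein_id: r.sequence for r in state.records}
        hits = profiles.scan(
            list(state.models.values()), seq_of,
            config.scan_seq_evalue_max, config.scan_dom_evalue_max,
        )
        _write_domain_hits(hits, paths[0])
        state.domain_hits = hits

    def scan_load(paths):
        state.domain_hits = _read_domain_hits(paths[0])

    stage("scan", ["domain_hits.tsv"], scan_compute, scan_load)

    # ------------------------------------------------------------------- clans
    def clans_compute(paths):
        models = list(state.models.values())
        pp = profiles.all_vs_all_profiles(
            models, rng_seed=config.rng_seed + 5, n_shuffles=config.pp_shuffles,
        )
        fg = superfamily.build_family_graph(
            pp, [m.model_id for m in models],
            config.clan_e_thick, config.clan_e_thin, config.clan_prob_dotted,
        )
        cluster_family = _cluster_majority_family(state)
        fam_sf = {f.family_id: f.superfamily_id for f in fams}
        seeds: dict[str, str] = {}
        for mid in sorted(state.models):
            fam = cluster_family.get(mid)
            sf = fam_sf.get(fam)
            if sf and sf not in seeds.values():
                seeds[mid] = sf
        assignments = superfamily.assign_clans(fg, seeds)
        superfamily.write_family_graph_tsv(fg, paths[0])
        superfamily.write_clans_tsv(assignments, paths[1])
        state.pp_hits = pp
        state.family_graph = fg
        state.clan_assignments = assignments
        state.cluster_family = cluster_family

    def clans_load(paths):
        clans_compute(paths)

    stage("clans", ["family_graph.tsv", "clans.tsv"], clans_compute, clans_load)

    # ------------------------------------------------------------------ census
    def census_compute(paths):
        cluster_family = state.cluster_family or _cluster_majority_family(state)
        fam_kind = {f.family_id: f.kind for f in fams}
        model_kind = {
            mid: fam_kind.get(cluster_family.get(mid, ""), "single")
            for mid in state.models
        }
        resolved = census_mod.resolve_overlaps(state.domain_hits, state.regions)
        lengths = census_mod.length_distribution(
            resolved, model_kind, config.length_band_halfwidth
        )
        records, freq, orphans = census_mod.coverage_table(resolved, state.regions)
        fam_sf = {f.family_id: f.superfamily_id for f in fams}
        fam_counts, sf_counts = census_mod.abundance_ranking(
            state.domain_hits, state.regions,
            family_of_model=cluster_family,
            superfamily_of_family=fam_sf,
        )
        protein_taxon = {r.protein_id: r.taxon_id for r in state.records}
        taxon_proteins: dict[str, int] = {}
        for r in state.records:
            taxon_proteins[r.taxon_id] = taxon_proteins.get(r.taxon_id, 0) + 1
        matrix, clade = census_mod.phyletic_matrix(
            state.domain_hits, protein_taxon, taxon_proteins,
            family_of_model=cluster_family,
            min_proteins=config.phyletic_min_proteins,
        )
        lengths.to_csv(paths[0], sep="\t", index=False)
        freq.to_csv(paths[1], sep="\t", index=False)
        fam_counts.to_csv(paths[2], sep="\t", index=False)
        matrix.to_csv(paths[3], sep="\t", index=False)
        state.results = {
            "lengths": lengths, "coverage_freq": freq, "coverage_orphans": orphans,
            "abundance_family": fam_counts, "abundance_superfamily": sf_counts,
            "phyletic": matrix, "phyletic_clade": clade,
        }

    def census_load(paths):
        census_compute(paths)

    stage(
        "census",
        ["length_distribution.tsv", "coverage_bins.tsv", "abundance.tsv", "phyletic.tsv"],
        census_compute, census_load,
    )

    manifest.state = state
    return manifest


def _cluster_majority_family(state: PipelineState) -> dict[str, str]:
    """Map each (possibly merged) model id to its majority planted family."""
    truth_by = {t.protein_id: t for t in state.truth}
    member_cluster: dict[str, set[str]] = {}
    for c in state.filtered:
        for m in c.members:
            member_cluster.setdefault(c.cluster_id, set()).add(m)
    out = {}
    for mid in state.models:
        members: set[str] = set()
        for part in mid.split("+"):
            members |= member_cluster.get(part, set())
        fams = []
        for rid in members:
            tr = truth_by.get(rid.split("/")[0])
            if tr is not None and tr.cls == "sensor-bearing" and tr.family_id:
                fams.append(tr.family_id)
        if fams:
            out[mid] = max(sorted(set(fams)), key=fams.count)
    return out


# ---------------------------------------------------------------------------
# serialization helpers


def _read_fasta_records(path: Path) -> list:
    records = []
    pid = taxon = None
    chunks: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if pid is not None:
                records.append(synthetic.ProteinRecord(pid, taxon, "".join(chunks)))
            fields = line[1:].split()
            pid = fields[0]
            taxon = ""
            for f in fields[1:]:
                if f.startswith("taxon="):
                    taxon = f[6:]
            chunks = []
        else:
            chunks.append(line.strip())
    if pid is not None:
        records.append(synthetic.ProteinRecord(pid, taxon, "".join(chunks)))
    return records


def _write_models(models: dict, path: Path) -> None:
    payload = {mid: json.loads(profiles.model_to_json(m)) for mid, m in models.items()}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _read_models(path: Path) -> dict:
    payload = json.loads(path.read_text())
    return {
        mid: profiles.model_from_json(json.dumps(d)) for mid, d in payload.items()
    }


def _write_alignments(aligns: dict, path: Path) -> None:
    payload = {
        aid: {"ids": list(a.ids), "rows": list(a.rows), "source": a.source_cluster}
        for aid, a in aligns.items()
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _read_alignments(path: Path) -> dict:
    payload = json.loads(path.read_text())
    return {
        aid: profiles.Alignment(
            tuple(d["ids"]), tuple(d["rows"]), source_cluster=d.get("source", "")
        )
        for aid, d in payload.items()
    }


DOMAIN_HITS_COLUMNS = ["protein", "model", "start", "end", "bits", "seq_E", "dom_E"]


def _write_domain_hits(hits: list, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DOMAIN_HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.model_id}\t{h.start}\t{h.end}\t"
                f"{h.bitscore:.4f}\t{h.seq_evalue:.6e}\t{h.dom_evalue:.6e}\n"
            )


def _read_domain_hits(path: Path) -> list:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DOMAIN_HITS_COLUMNS:
            raise ValueError(f"domain hits TSV: unexpected header {header}")
        for line in fh:
            p, m, s, e, b, se, de = line.rstrip("\n").split("\t")
            hits.append(
                profiles.DomainHit(p, m, int(s), int(e), float(b), float(se), float(de))
            )
    return hits
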