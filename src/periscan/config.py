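"""Pipeline configuration: every threshold in one validated, serialisable place.

Defaults are the thresholds conventionally used for this kind of census:
candidate regions longer than 50 residues (strict), redundancy removal at
90% identity, similarity-graph edges at E < 1e-10 with reciprocal coverage
> 95%, clusters of at least 10 members, detection at sequence/domain
E-values of 1e-3, clan tiers at 1e-3 / 1e-1 / probability 90, heat-map
floor 20.  The synthetic benchmark overrides only the scale-dependent keys
(phyletic protein floor, calibration sizes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # synthetic universe
    n_proteins: int = 300
    n_taxa: int = 8
    rng_seed: int = 1
    ancestor_divergence: float = 0.7
    anchor_fraction: float = 0.55

    # topology stand-in
    hydropathy_window: int = 19
    hydropathy_threshold: float = 1.6
    min_tm_run: int = 1
    n_terminus: str = "inside"

    # region extraction
    min_region_length: int = 50  # strict: keep length >= min+1

    # redundancy + similarity network
    redundancy_identity: float = 0.90
    graph_evalue_max: float = 1e-10
    graph_coverage_min: float = 0.95
    cluster_min_size: int = 10

    # representative selection (independent keys; defaults follow the graph)
    represent_evalue_max: float = 1e-10
    represent_coverage_min: float = 0.95

    # profile construction / calibration / scanning
    match_fraction: float = 0.5
    pseudocount_weight: float = 1.5
    calibration_n: int = 300
    calibration_length: int = 200
    scan_seq_evalue_max: float = 1e-3
    scan_dom_evalue_max: float = 1e-3

    # profile-profile comparison / merging / clan tiers
    pp_shuffles: int = 100
    merge_probability_min: float = 90.0
    merge_coverage_min: float = 0.6
    merge_min_bits_per_column: float = 2.0
    clan_e_thick: float = 1e-3
    clan_e_thin: float = 1e-1
    clan_prob_dotted: float = 90.0
    heatmap_prob_floor: float = 20.0

    # census
    phyletic_min_proteins: int = 1000
    length_band_halfwidth: float = 0.35

    def validate(self) -> None:
        checks = [
            (self.n_proteins >= 1, "n_proteins >= 1"),
            (self.min_region_length >= 0, "min_region_length >= 0"),
            (0 < self.redundancy_identity <= 1, "redundancy_identity in (0,1]"),
            (self.graph_evalue_max > 0, "graph_evalue_max > 0"),
            (0 <= self.graph_coverage_min <= 1, "graph_coverage_min in [0,1]"),
            (self.cluster_min_size >= 1, "cluster_min_size >= 1"),
            (0 < self.match_fraction <= 1, "match_fraction in (0,1]"),
            (self.calibration_n >= 200, "calibration_n >= 200"),
            (self.scan_seq_evalue_max > 0, "scan_seq_evalue_max > 0"),
            (0 <= self.merge_probability_min <= 100, "merge_probability_min in [0,100]"),
            (0 <= self.clan_prob_dotted <= 100, "clan_prob_dotted in [0,100]"),
            (self.clan_e_thick <= self.clan_e_thin, "clan tiers must nest"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config violates: {msg}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())


def default_synthetic_config(rng_seed: int = 1, n_proteins: int = 300) -> PipelineConfig:
    """Study conditions for the bundled synthetic benchmark.

    The phyletic protein floor is scaled to the synthetic proteome size
    (taxa carry tens of proteins, not thousands).
    """
    return PipelineConfig(
        rng_seed=rng_seed,
        n_proteins=n_proteins,
        phyletic_min_proteins=20,
    )
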