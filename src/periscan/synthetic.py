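"""Synthetic proteome generator with planted sensor-domain families.

Real censuses of extracellular sensor domains run against whole protein
databases.  This module emulates that universe at desk scale: proteomes of
membrane receptors with the layout

    N-tail(in) - TM - sensor domain(out) - TM - linker(in) - output domain - C-tail

plus intracellular decoys (a family-like domain placed cytoplasmically) and
sensor-less decoys (a random extracellular loop between two TMs), together
with a machine-readable ground-truth table.  Families can share a
superfamily ancestor so that profile-profile relationships, clan assignment
and subdomain experiments are exercisable downstream.

All randomness flows from one integer seed; per-protein substreams are
derived by spawning the seed with the protein index, so generation is
reproducible and order-independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as _KD

from .constants import AMINO_ACIDS, SOLUBLE_BACKGROUND, TM_RESIDUES, TM_WEIGHTS

__all__ = [
    "FamilySpec",
    "ArchitectureSpec",
    "FamilyConsensus",
    "ProteinRecord",
    "TruthRow",
    "generate_family_consensus",
    "generate_consensi",
    "fuse_consensi",
    "sample_family_member",
    "generate_proteome",
    "default_families",
    "default_architecture",
    "write_fasta",
    "write_truth_table",
    "read_truth_table",
]

#: Default output-domain consensus: a fixed cytoplasmic effector motif of 60
#: residues (generated once from the background at a frozen seed and embedded
#: as a constant so every simulated proteome shares one output-domain family).
DEFAULT_OUTPUT_MOTIF = (
    "MKELGHSVRDQNTAYWFPLICGAKESTVRDLMHQNYFGIWPSACDEKLRTVGHMNQSYAI"
)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one planted sensor-domain family."""

    family_id: str
    kind: str = "single"  # "single" (~140 aa) or "double" (~271 aa tandem)
    domain_length: int = 140
    n_seed_sequences: int = 40
    divergence: float = 0.25  # expected substitutions/site from consensus
    superfamily_id: str | None = None

    def validate(self) -> None:
        if self.kind not in ("single", "double"):
            raise ValueError(f"kind must be 'single' or 'double', got {self.kind!r}")
        if self.domain_length < 30:
            raise ValueError("domain_length must be >= 30")
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence must lie in (0, 1)")
        if self.n_seed_sequences < 1:
            raise ValueError("n_seed_sequences must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Composition of the simulated proteome."""

    n_proteins: int = 300
    fraction_sensor_bearing: float = 0.8
    fraction_intracellular_decoys: float = 0.1
    output_domain_motif: str = DEFAULT_OUTPUT_MOTIF
    tm_length: int = 21
    loop_length_range: tuple[int, int] = (15, 40)
    decoy_loop_length_range: tuple[int, int] = (60, 120)

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for f in (self.fraction_sensor_bearing, self.fraction_intracellular_decoys):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_sensor_bearing + self.fraction_intracellular_decoys > 1.0 + 1e-12:
            raise ValueError("architecture fractions sum to more than 1")
        if self.tm_length < 15:
            raise ValueError("tm_length must be >= 15")
        lo, hi = self.loop_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid loop_length_range")


@dataclass(frozen=True)
class FamilyConsensus:
    """A family consensus sequence plus metadata.

    For ``kind='double'`` the consensus is a tandem of two subdomains and
    ``subdomain_boundary`` is the 0-based index of the first residue of the
    membrane-proximal (C-terminal) subdomain.
    """

    family_id: str
    sequence: str
    kind: str = "single"
    subdomain_boundary: int | None = None
    superfamily_id: str | None = None


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    taxon_id: str
    sequence: str


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one emitted protein.

    ``region_start``/``region_end`` are 1-based inclusive coordinates of the
    planted domain (sensor-bearing and intracellular-decoy classes) or of the
    random extracellular loop (sensorless class); 0/0 if neither applies.
    ``topology`` is the true segment string, e.g. ``i1-25;M26-46;o47-190;...``.
    """

    protein_id: str
    taxon_id: str
    cls: str  # sensor-bearing | intracellular-decoy | sensorless
    family_id: str  # "" when no family planted
    region_start: int
    region_end: int
    topology: str


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for one simulation sub-task."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    """Soluble-segment residues: hydrophobic-depleted background composition."""
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=SOLUBLE_BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _max_window_hydropathy(seq: str, window: int = 19) -> float:
    if len(seq) < window:
        return -np.inf
    sc = np.array([_KD.get(c, 0.0) for c in seq])
    return float(np.convolve(sc, np.ones(window) / window, mode="valid").max())


#: Consensi are rejected while any 19-residue window exceeds this mean
#: hydropathy: a soluble extracellular domain with a TM-grade hydrophobic
#: stretch would be (mis)called as membrane by any hydropathy method, and
#: such domains are excluded from the simulated universe by construction.
MAX_DOMAIN_WINDOW_HYDROPATHY = 0.2


def _max_hydrophobic_run(seq: str, cutoff: float = 1.0) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if _KD.get(c, 0.0) >= cutoff else 0
        best = max(best, cur)
    return best


def _is_clean(seq: str) -> bool:
    """Hydropathy cleanliness for simulated soluble domains.

    No 19-residue window may reach TM-grade mean hydropathy, and no more
    than two consecutive residues may be strongly hydrophobic — a longer run
    adjacent to a helix would be indistinguishable from the helix itself.
    """
    return (
        _max_window_hydropathy(seq) < MAX_DOMAIN_WINDOW_HYDROPATHY
        and _max_hydrophobic_run(seq) <= 2
    )


def _clean_soluble_seq(rng: np.random.Generator, length: int, max_tries: int = 2000) -> str:
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if _is_clean(seq):
            return seq
    raise RuntimeError("could not draw a hydropathy-clean consensus")


def _tm_segment(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(TM_RESIDUES), size=length, p=TM_WEIGHTS)
    return "".join(TM_RESIDUES[i] for i in idx)


def generate_family_consensus(spec: FamilySpec, rng_seed: int) -> FamilyConsensus:
    """Draw a family consensus from the background composition.

    The emitted length is uniform within +/-10% of ``spec.domain_length``.
    Double families are tandems of two independently drawn subdomains of
    half length each, with the boundary recorded in the metadata.
    """
    spec.validate()
    rng = _substream(rng_seed, 0)
    if spec.kind == "single":
        lo, hi = round(0.9 * spec.domain_length), round(1.1 * spec.domain_length)
        length = int(rng.integers(lo, hi + 1))
        return FamilyConsensus(
            spec.family_id, _clean_soluble_seq(rng, length), "single", None,
            spec.superfamily_id,
        )
    half = spec.domain_length / 2.0
    lo, hi = round(0.9 * half), round(1.1 * half)
    n_len = int(rng.integers(lo, hi + 1))
    c_len = int(rng.integers(lo, hi + 1))
    n_sub = _clean_soluble_seq(rng, n_len)
    c_sub = _clean_soluble_seq(rng, c_len)
    return FamilyConsensus(
        spec.family_id, n_sub + c_sub, "double", n_len, spec.superfamily_id
    )


def fuse_consensi(
    family_id: str, n_source: FamilyConsensus, c_source: FamilyConsensus,
    superfamily_id: str | None = None,
) -> FamilyConsensus:
    """Build a double-domain consensus by fusing two single-family consensi.

    The N-terminal (membrane-distal) half is ``n_source`` and the C-terminal
    (membrane-proximal) half is ``c_source``; the fusion boundary is recorded.
    """
    return FamilyConsensus(
        family_id,
        n_source.sequence + c_source.sequence,
        "double",
        len(n_source.sequence),
        superfamily_id,
    )


def sample_family_member(
    consensus: str,
    divergence: float,
    rng_seed: int | np.random.Generator,
    indel_rate: float = 0.01,
    indel_mean_length: float = 2.0,
) -> str:
    """Sample one family member from a consensus.

    Each site is substituted with probability ``divergence``; the replacement
    is drawn from the background distribution conditioned on differing from
    the consensus residue, so expected identity to the consensus is
    approximately ``1 - divergence``.  Small indels occur at ``indel_rate``
    per site (half insertions, half deletions) with geometric lengths of mean
    ``indel_mean_length``; set ``indel_rate=0`` for substitution-only
    sampling.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    if not (0.0 < divergence < 1.0):
        raise ValueError("divergence must lie in (0, 1)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else _substream(rng_seed, 1)
    )
    geom_p = 1.0 / indel_mean_length  # mean of geometric(p) on {1,2,...} is 1/p
    out: list[str] = []
    pos = 0
    n = len(consensus)
    while pos < n:
        if indel_rate > 0 and rng.random() < indel_rate / 2.0:
            pos += int(rng.geometric(geom_p))  # deletion of geometric length
            continue
        ch = consensus[pos]
        if rng.random() < divergence:
            i = AMINO_ACIDS.index(ch) if ch in AMINO_ACIDS else -1
            p = SOLUBLE_BACKGROUND.copy()
            if i >= 0:
                p[i] = 0.0
                p /= p.sum()
            out.append(AMINO_ACIDS[int(rng.choice(len(AMINO_ACIDS), p=p))])
        else:
            out.append(ch)
        if indel_rate > 0 and rng.random() < indel_rate / 2.0:
            out.append(_random_seq(rng, int(rng.geometric(geom_p))))
        pos += 1
    return "".join(out)


def generate_consensi(
    families: list[FamilySpec],
    rng_seed: int,
    ancestor_divergence: float = 0.7,
    anchor_fraction: float = 0.55,
    core_fraction: float = 0.6,
    periphery_length_range: tuple[int, int] = (15, 40),
) -> dict[str, FamilyConsensus]:
    """Generate consensi for a family set, honouring superfamily structure.

    Families sharing a ``superfamily_id`` descend from a common *core*
    ancestor sampled once per superfamily (length ``core_fraction`` of the
    family domain length).  Within the core, a fraction ``anchor_fraction``
    of positions are the superfamily's conserved motif set, inherited
    unchanged by every family consensus; the remaining core positions
    substitute at ``ancestor_divergence`` per site.  Each family then adds
    its own unrelated periphery — fresh random flanks of family-specific
    length drawn from ``periphery_length_range`` — mirroring how real
    superfamilies share a structural core while the membrane-adjacent
    periphery is family-specific.  The periphery is what keeps members of
    different families from aligning end-to-end: cross-family similarity is
    confined to the core and cannot reach reciprocal full coverage.

    Single families are periphery+core+periphery; double families are
    tandems of two such units derived independently from the same core
    ancestor.  Families without a superfamily (or alone in theirs) get
    independent consensi via :func:`generate_family_consensus`.
    """
    by_sf: dict[str, list[FamilySpec]] = {}
    for spec in families:
        spec.validate()
        if spec.superfamily_id is not None:
            by_sf.setdefault(spec.superfamily_id, []).append(spec)

    ancestors: dict[str, tuple[str, np.ndarray]] = {}
    for k, (sf, members) in enumerate(sorted(by_sf.items())):
        if len(members) < 2:
            continue
        single_equiv = [
            s.domain_length if s.kind == "single" else s.domain_length // 2
            for s in members
        ]
        rng = _substream(rng_seed, 100 + k)
        core_len = int(round(core_fraction * float(np.mean(single_equiv))))
        core = _clean_soluble_seq(rng, core_len)
        n_anchor = int(round(anchor_fraction * core_len))
        anchors = np.sort(rng.choice(core_len, size=n_anchor, replace=False))
        ancestors[sf] = (core, anchors)

    consensi: dict[str, FamilyConsensus] = {}
    plo, phi = periphery_length_range
    for j, spec in enumerate(families):
        anc = ancestors.get(spec.superfamily_id or "")
        if anc is None:
            consensi[spec.family_id] = generate_family_consensus(
                spec, rng_seed * 1000 + j
            )
            continue
        core_seq, anchors = anc
        anchor_set = set(int(i) for i in anchors)
        rng = _substream(rng_seed, 200 + j)

        def unit() -> str:
            """periphery + derived core + periphery, hydropathy-clean."""
            for _ in range(2000):
                seq = (
                    _random_seq(rng, int(rng.integers(plo, phi + 1)))
                    + _derive_consensus(core_seq, anchor_set, ancestor_divergence, rng)
                    + _random_seq(rng, int(rng.integers(plo, phi + 1)))
                )
                if _is_clean(seq):
                    return seq
            raise RuntimeError("could not draw a hydropathy-clean consensus")

        if spec.kind == "single":
            consensi[spec.family_id] = FamilyConsensus(
                spec.family_id, unit(), "single", None, spec.superfamily_id
            )
        else:
            n_sub = unit()
            c_sub = unit()
            consensi[spec.family_id] = FamilyConsensus(
                spec.family_id, n_sub + c_sub, "double", len(n_sub), spec.superfamily_id
            )
    return consensi


def _derive_consensus(
    ancestor: str, anchor_positions: set[int], divergence: float,
    rng: np.random.Generator,
) -> str:
    """Family consensus from a superfamily ancestor.

    Anchor (conserved-core) positions are copied verbatim; the rest
    substitute with probability ``divergence``.  No indels, so anchors stay
    columnwise comparable across the superfamily.
    """
    out = []
    for i, ch in enumerate(ancestor):
        if i in anchor_positions or rng.random() >= divergence:
            out.append(ch)
        else:
            p = SOLUBLE_BACKGROUND.copy()
            k = AMINO_ACIDS.index(ch)
            p[k] = 0.0
            p /= p.sum()
            out.append(AMINO_ACIDS[int(rng.choice(len(AMINO_ACIDS), p=p))])
    return "".join(out)


def _topology_string(segments: list[tuple[str, int, int]]) -> str:
    return ";".join(f"{lab}{s}-{e}" for lab, s, e in segments)


def generate_proteome(
    arch: ArchitectureSpec,
    families: list[FamilySpec],
    n_taxa: int = 8,
    rng_seed: int = 0,
    consensi: dict[str, FamilyConsensus] | None = None,
    ancestor_divergence: float = 0.7,
    anchor_fraction: float = 0.55,
) -> tuple[list[ProteinRecord], list[TruthRow], dict]:
    """Emit a proteome with planted families plus its ground-truth table.

    Returns ``(records, truth, meta)`` where ``meta`` records the generation
    parameters, the family consensi and the per-family taxon presence
    pattern.  Sensor proteins are assigned round-robin to families so member
    counts are exact; each protein's taxon is drawn from the taxa where its
    family is present.
    """
    arch.validate()
    if not families:
        raise ValueError("at least one family required")
    for spec in families:
        spec.validate()
    if consensi is None:
        consensi = generate_consensi(families, rng_seed, ancestor_divergence, anchor_fraction)

    n_sensor = round(arch.n_proteins * arch.fraction_sensor_bearing)
    n_intra = round(arch.n_proteins * arch.fraction_intracellular_decoys)
    if n_sensor + n_intra > arch.n_proteins:
        n_intra = arch.n_proteins - n_sensor
    n_less = arch.n_proteins - n_sensor - n_intra

    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    rng0 = _substream(rng_seed, 2)
    family_taxa: dict[str, list[str]] = {}
    for spec in families:
        present = [t for t in taxa if rng0.random() < 0.6]
        if not present:
            present = [taxa[int(rng0.integers(0, n_taxa))]]
        family_taxa[spec.family_id] = present

    lo, hi = arch.loop_length_range
    dlo, dhi = arch.decoy_loop_length_range
    records: list[ProteinRecord] = []
    truth: list[TruthRow] = []

    classes = (
        ["sensor-bearing"] * n_sensor
        + ["intracellular-decoy"] * n_intra
        + ["sensorless"] * n_less
    )
    for idx, cls in enumerate(classes):
        rng = _substream(rng_seed, 3, idx)
        pid = f"prot{idx:05d}"
        spec = families[idx % len(families)]
        cons = consensi[spec.family_id]

        def loop(n_lo=lo, n_hi=hi):
            return _random_seq(rng, int(rng.integers(n_lo, n_hi + 1)))

        if cls == "sensor-bearing":
            taxon = str(rng.choice(family_taxa[spec.family_id]))
            domain = sample_family_member(cons.sequence, spec.divergence, rng)
            n_tail = loop()
            tm1 = _tm_segment(rng, arch.tm_length)
            tm2 = _tm_segment(rng, arch.tm_length)
            linker = loop()
            output = sample_family_member(arch.output_domain_motif, 0.05, rng, indel_rate=0.0)
            c_tail = loop(10, 30)
            seq = n_tail + tm1 + domain + tm2 + linker + output + c_tail
            a = len(n_tail)
            b = a + len(tm1)
            c = b + len(domain)
            d = c + len(tm2)
            segs = [
                ("i", 1, a),
                ("M", a + 1, b),
                ("o", b + 1, c),
                ("M", c + 1, d),
                ("i", d + 1, len(seq)),
            ]
            truth.append(
                TruthRow(pid, taxon, cls, spec.family_id, b + 1, c, _topology_string(segs))
            )
        elif cls == "intracellular-decoy":
            taxon = str(rng.choice(taxa))
            domain = sample_family_member(cons.sequence, spec.divergence, rng)
            n_tail = loop()
            mid = loop()
            tm1 = _tm_segment(rng, arch.tm_length)
            short_out = loop(15, 30)
            tm2 = _tm_segment(rng, arch.tm_length)
            linker = loop()
            output = sample_family_member(arch.output_domain_motif, 0.05, rng, indel_rate=0.0)
            seq = n_tail + domain + mid + tm1 + short_out + tm2 + linker + output
            a = len(n_tail) + len(domain) + len(mid)
            b = a + len(tm1)
            c = b + len(short_out)
            d = c + len(tm2)
            segs = [
                ("i", 1, a),
                ("M", a + 1, b),
                ("o", b + 1, c),
                ("M", c + 1, d),
                ("i", d + 1, len(seq)),
            ]
            truth.append(
                TruthRow(
                    pid, taxon, cls, spec.family_id,
                    len(n_tail) + 1, len(n_tail) + len(domain),
                    _topology_string(segs),
                )
            )
        else:  # sensorless decoy: random extracellular loop between two TMs
            taxon = str(rng.choice(taxa))
            n_tail = loop()
            tm1 = _tm_segment(rng, arch.tm_length)
            decoy = _random_seq(rng, int(rng.integers(dlo, dhi + 1)))
            tm2 = _tm_segment(rng, arch.tm_length)
            linker = loop()
            output = sample_family_member(arch.output_domain_motif, 0.05, rng, indel_rate=0.0)
            seq = n_tail + tm1 + decoy + tm2 + linker + output
            a = len(n_tail)
            b = a + len(tm1)
            c = b + len(decoy)
            d = c + len(tm2)
            segs = [
                ("i", 1, a),
                ("M", a + 1, b),
                ("o", b + 1, c),
                ("M", c + 1, d),
                ("i", d + 1, len(seq)),
            ]
            truth.append(
                TruthRow(pid, taxon, cls, "", b + 1, c, _topology_string(segs))
            )
        records.append(ProteinRecord(pid, taxon, seq))

    meta = {
        "rng_seed": rng_seed,
        "anchor_fraction": anchor_fraction,
        "architecture": dataclasses.asdict(arch),
        "families": [dataclasses.asdict(s) for s in families],
        "ancestor_divergence": ancestor_divergence,
        "family_taxa": family_taxa,
        "consensi": {
            fid: dataclasses.asdict(c) for fid, c in consensi.items()
        },
    }
    return records, truth, meta


def default_families() -> list[FamilySpec]:
    """The default study conditions: six families in two superfamilies.

    Five single-domain families (~140 aa) and one double (tandem ~271 aa),
    forty members each at 0.25 substitutions/site divergence.
    """
    return [
        FamilySpec("FamA1", "single", 140, 40, 0.25, "SFA"),
        FamilySpec("FamA2", "single", 140, 40, 0.25, "SFA"),
        FamilySpec("FamA3", "single", 140, 40, 0.25, "SFA"),
        FamilySpec("FamB1", "single", 140, 40, 0.25, "SFB"),
        FamilySpec("FamB2", "single", 140, 40, 0.25, "SFB"),
        FamilySpec("FamB3", "double", 271, 40, 0.25, "SFB"),
    ]


def default_architecture(n_proteins: int = 300) -> ArchitectureSpec:
    return ArchitectureSpec(n_proteins=n_proteins)


# ---------------------------------------------------------------------------
# I/O


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """FASTA wrapped at 60 columns; taxon carried in the description."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id} taxon={rec.taxon_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


TRUTH_COLUMNS = [
    "protein_id", "taxon_id", "class", "family_id",
    "region_start", "region_end", "topology",
]


def write_truth_table(truth: list[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in truth:
            fh.write(
                "\t".join(
                    [r.protein_id, r.taxon_id, r.cls, r.family_id,
                     str(r.region_start), str(r.region_end), r.topology]
                )
                + "\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRow]:
    rows: list[TruthRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in TRUTH_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"truth table missing column(s): {', '.join(missing)}")
        pos = {c: header.index(c) for c in TRUTH_COLUMNS}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(
                TruthRow(
                    f[pos["protein_id"]], f[pos["taxon_id"]], f[pos["class"]],
                    f[pos["family_id"]], int(f[pos["region_start"]]),
                    int(f[pos["region_end"]]), f[pos["topology"]],
                )
            )
    return rows


def write_meta(meta: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
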