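"""Membrane topology and extraction of candidate extracellular regions.

Real pipelines use dedicated transmembrane-topology predictors; this module
provides (a) a built-in hydropathy stand-in — sliding-window Kyte-Doolittle
averaging with a fixed threshold — and (b) an import path for precomputed
topology annotations in TSV form, so output from any external predictor can
be used instead.

A candidate sensor region is an *outside* segment lying strictly between two
membrane segments and longer than 50 residues (strict reading: length >= 51,
configurable).  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "Segment",
    "TopologyAnnotation",
    "ExtracellularRegion",
    "predict_topology",
    "extract_regions",
    "filter_sensor_context",
    "classify_localization",
    "write_topology_tsv",
    "read_topology_tsv",
    "write_regions_fasta",
    "read_regions_fasta",
]

INSIDE, MEMBRANE, OUTSIDE = "inside", "membrane", "outside"


@dataclass(frozen=True)
class Segment:
    label: str  # inside | membrane | outside
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class TopologyAnnotation:
    protein_id: str
    segments: tuple[Segment, ...]

    def validate(self, sequence_length: int | None = None) -> None:
        if not self.segments:
            raise ValueError("annotation has no segments")
        prev_end = 0
        prev_label = None
        for seg in self.segments:
            if seg.start != prev_end + 1:
                raise ValueError(
                    f"segments do not tile: gap/overlap before {seg.start}"
                )
            if seg.label == MEMBRANE and prev_label == MEMBRANE:
                raise ValueError("two adjacent membrane segments")
            prev_end = seg.end
            prev_label = seg.label
        if sequence_length is not None and prev_end != sequence_length:
            raise ValueError(
                f"annotation covers {prev_end} residues, sequence has {sequence_length}"
            )


@dataclass(frozen=True)
class ExtracellularRegion:
    """An outside segment flanked by two TM helices (TM residues excluded)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    tm_pair_index: int  # 0-based index of the flanking TM pair (N->C order)

    @property
    def region_id(self) -> str:
        return f"{self.protein_id}/{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def predict_topology(
    protein_id: str,
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_tm_run: int = 1,
    merge_gap: int = 10,
    refine_center: float = 2.0,
    n_terminus: str = INSIDE,
) -> TopologyAnnotation:
    """Hydropathy-based topology stand-in.

    Mean Kyte-Doolittle hydropathy is computed in a sliding window of
    ``window`` residues; maximal runs of at least ``min_tm_run`` consecutive
    window centres above ``threshold`` become candidate membrane segments.
    Candidate segments separated by fewer than ``merge_gap`` below-threshold
    centres are merged (a single noisy window inside a helix must not split
    it), and each segment's boundaries are then refined to the maximal-sum
    stretch of per-residue hydropathy minus ``refine_center`` around the run
    — the sliding window alone blurs helix ends by several residues.

    Loop segments alternate inside/outside starting from the stated
    N-terminal orientation (default "inside", matching the simulated
    architectures; real predictors model orientation explicitly and their
    output can be imported via :func:`read_topology_tsv` instead).

    A sequence shorter than the window yields a single loop segment.
    """
    if n_terminus not in (INSIDE, OUTSIDE):
        raise ValueError("n_terminus must be 'inside' or 'outside'")
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    if n < window:
        return TopologyAnnotation(protein_id, (Segment(n_terminus, 1, n),))

    scores = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in sequence], dtype=float)
    kernel = np.ones(window) / window
    means = np.convolve(scores, kernel, mode="valid")  # centre i -> window i..i+w-1
    half = (window - 1) // 2
    above = np.zeros(n, dtype=bool)
    above[half : half + len(means)] = means > threshold

    # maximal runs of above-threshold centres (0-based, inclusive)
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_tm_run:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1

    # merge runs separated by short dips
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    # refine boundaries by per-residue hydropathy around each run
    centred = scores - refine_center
    refined: list[tuple[int, int]] = []
    for k, (s, e) in enumerate(merged):
        mid = (s + e) // 2
        lo = 0 if k == 0 else (merged[k - 1][1] + mid) // 2 + 1
        hi = n - 1 if k == len(merged) - 1 else (mid + merged[k + 1][0]) // 2
        lo = max(lo, mid - (window - 1), 0)
        hi = min(hi, mid + (window - 1), n - 1)
        # best start: maximise suffix sum ending at mid; best end symmetric
        best_s, best = mid, -np.inf
        acc = 0.0
        for p in range(mid, lo - 1, -1):
            acc += centred[p]
            if acc >= best:
                best, best_s = acc, p
        best_e, best = mid, -np.inf
        acc = 0.0
        for p in range(mid, hi + 1):
            acc += centred[p]
            if acc >= best:
                best, best_e = acc, p
        refined.append((best_s + 1, best_e + 1))  # 1-based

    segments: list[Segment] = []
    loop_label = n_terminus
    pos = 1
    for s, e in refined:
        if s > pos:
            segments.append(Segment(loop_label, pos, s - 1))
            loop_label = OUTSIDE if loop_label == INSIDE else INSIDE
            segments.append(Segment(MEMBRANE, s, e))
        elif segments and segments[-1].label == MEMBRANE:
            # refined segments touching: fuse into one helix
            segments[-1] = Segment(MEMBRANE, segments[-1].start, e)
        else:
            segments.append(Segment(MEMBRANE, s, e))
        pos = e + 1
    if pos <= n:
        segments.append(Segment(loop_label, pos, n))
    ann = TopologyAnnotation(protein_id, tuple(segments))
    ann.validate(n)
    return ann


def extract_regions(
    annotation: TopologyAnnotation,
    sequence: str,
    min_length: int = 50,
) -> list[ExtracellularRegion]:
    """Extract outside segments strictly between two membrane segments.

    The length filter follows the strict reading of "longer than
    ``min_length``": a region of exactly ``min_length`` residues is
    rejected, ``min_length + 1`` is kept.  Regions are returned in N->C
    order; the flanking TM segments are excluded from the coordinates.
    """
    annotation.validate(len(sequence))
    segs = annotation.segments
    regions: list[ExtracellularRegion] = []
    tm_pair = 0
    for k in range(1, len(segs) - 1):
        seg = segs[k]
        if (
            seg.label == OUTSIDE
            and segs[k - 1].label == MEMBRANE
            and segs[k + 1].label == MEMBRANE
        ):
            if seg.end - seg.start + 1 > min_length:
                regions.append(
                    ExtracellularRegion(
                        annotation.protein_id,
                        seg.start,
                        seg.end,
                        sequence[seg.start - 1 : seg.end],
                        tm_pair,
                    )
                )
            tm_pair += 1
    return regions


def filter_sensor_context(
    regions: list[ExtracellularRegion],
    output_hits,
) -> list[ExtracellularRegion]:
    """Keep regions whose protein has an output-domain hit elsewhere.

    ``output_hits`` is an iterable of objects/tuples with ``protein_id``,
    ``start``, ``end`` attributes (e.g. DomainHit rows for output-domain
    models, or an imported table).  A hit counts only if it lies outside the
    region's own coordinates — the output domain must be a separate module
    of the protein, not the region itself.
    """
    by_protein: dict[str, list[tuple[int, int]]] = {}
    for h in output_hits:
        pid = getattr(h, "protein_id", None) or h[0]
        s = int(getattr(h, "start", None) if hasattr(h, "start") else h[1])
        e = int(getattr(h, "end", None) if hasattr(h, "end") else h[2])
        by_protein.setdefault(pid, []).append((s, e))
    kept = []
    for r in regions:
        for s, e in by_protein.get(r.protein_id, []):
            if e < r.start or s > r.end:  # hit entirely outside the region
                kept.append(r)
                break
    return kept


def classify_localization(
    hits,
    annotations: dict[str, TopologyAnnotation],
    model_to_family: dict[str, str] | None = None,
) -> "pd.DataFrame":
    """Label each domain hit extracellular / intracellular / mixed / unknown.

    A hit is labelled by majority overlap of its envelope with outside
    versus inside segments of its protein's topology annotation; exact ties
    are "mixed".  Hits on proteins with no membrane segment are intracellular
    (everything is cytoplasmic by convention); hits on proteins lacking any
    annotation are "unknown" and counted separately.  Returns a per-hit
    table plus per-family fractions can be computed by grouping on
    ``family`` and ``localization``.
    """
    import pandas as pd

    rows = []
    for h in hits:
        pid, model, s, e = h.protein_id, h.model_id, h.start, h.end
        ann = annotations.get(pid)
        if ann is None:
            loc = "unknown"
        else:
            has_tm = any(seg.label == MEMBRANE for seg in ann.segments)
            if not has_tm:
                loc = "intracellular"
            else:
                out_ov = in_ov = 0
                for seg in ann.segments:
                    ov = max(0, min(e, seg.end) - max(s, seg.start) + 1)
                    if seg.label == OUTSIDE:
                        out_ov += ov
                    elif seg.label == INSIDE:
                        in_ov += ov
                if out_ov > in_ov:
                    loc = "extracellular"
                elif in_ov > out_ov:
                    loc = "intracellular"
                else:
                    loc = "mixed"
        fam = model_to_family.get(model, model) if model_to_family else model
        rows.append((pid, model, fam, s, e, loc))
    return pd.DataFrame(
        rows, columns=["protein_id", "model_id", "family", "start", "end", "localization"]
    )


def localization_fractions(per_hit: "pd.DataFrame") -> "pd.DataFrame":
    """Per-family fractions of each localization label."""
    counts = per_hit.groupby(["family", "localization"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# I/O


def write_topology_tsv(annotations, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlabel\tstart\tend\n")
        for ann in annotations:
            for seg in ann.segments:
                fh.write(f"{ann.protein_id}\t{seg.label}\t{seg.start}\t{seg.end}\n")


def read_topology_tsv(path: str | Path) -> dict[str, TopologyAnnotation]:
    per: dict[str, list[Segment]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in ("protein_id", "label", "start", "end"):
            if col not in header:
                raise ValueError(f"topology TSV missing column: {col}")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            per.setdefault(f[idx["protein_id"]], []).append(
                Segment(f[idx["label"]], int(f[idx["start"]]), int(f[idx["end"]]))
            )
    out = {}
    for pid, segs in per.items():
        ann = TopologyAnnotation(pid, tuple(sorted(segs, key=lambda s: s.start)))
        ann.validate()
        out[pid] = ann
    return out


def parse_topology_string(protein_id: str, topo: str) -> TopologyAnnotation:
    """Parse the compact truth-table form ``i1-25;M26-46;o47-190;...``."""
    label_map = {"i": INSIDE, "M": MEMBRANE, "o": OUTSIDE}
    segs = []
    for part in topo.split(";"):
        lab = label_map[part[0]]
        s, e = part[1:].split("-")
        segs.append(Segment(lab, int(s), int(e)))
    return TopologyAnnotation(protein_id, tuple(segs))


def write_regions_fasta(regions: list[ExtracellularRegion], path: str | Path) -> None:
    """Region FASTA with headers ``proteinid/start-end``."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.region_id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def read_regions_fasta(path: str | Path) -> list[ExtracellularRegion]:
    regions = []
    with open(path) as fh:
        header = None
        chunks: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    regions.append(_region_from_header(header, "".join(chunks)))
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if header is not None:
            regions.append(_region_from_header(header, "".join(chunks)))
    return regions


def _region_from_header(header: str, seq: str) -> ExtracellularRegion:
    try:
        pid, span = header.rsplit("/", 1)
        s, e = span.split("-")
        return ExtracellularRegion(pid, int(s), int(e), seq, 0)
    except ValueError as exc:
        raise ValueError(f"malformed region header {header!r}") from exc
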