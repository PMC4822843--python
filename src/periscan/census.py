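"""Census statistics over detected sensor domains.

Downstream bookkeeping once families have models and the proteome has been
scanned: per-family domain-length distributions with outlier flags, model
coverage of the extracellular regions (how much of each region the domain
explains), abundance ranking of families and superfamilies, and the
phyletic presence/absence matrix across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import DomainHit
from .topology import ExtracellularRegion

__all__ = [
    "CoverageRecord",
    "resolve_overlaps",
    "length_distribution",
    "coverage_table",
    "abundance_ranking",
    "phyletic_matrix",
]

#: Reference domain lengths for single and tandem (double) sensor domains.
SINGLE_LENGTH = 140
DOUBLE_LENGTH = 271


@dataclass(frozen=True)
class CoverageRecord:
    region_id: str
    model_id: str
    domain_length: int
    region_length: int
    coverage: float  # domain_length / region_length, clamped into (0, 1]
    bin: int  # floor(100*coverage/10); 100% falls in the top bin (9)


def resolve_overlaps(
    hits: list[DomainHit],
    regions: list[ExtracellularRegion],
) -> list[DomainHit]:
    """Clan-style competition: keep the best hit per extracellular region.

    Related family models legitimately cross-detect each other's members
    (they are homologs); for per-family statistics each region is credited
    to the best-scoring model only — lowest domain E-value, ties broken by
    model id.  Hits outside any region are dropped.
    """
    by_protein: dict[str, list[ExtracellularRegion]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    best: dict[str, DomainHit] = {}
    for h in hits:
        for r in by_protein.get(h.protein_id, []):
            if h.start <= r.end and h.end >= r.start:
                cur = best.get(r.region_id)
                if cur is None or (h.dom_evalue, h.model_id) < (cur.dom_evalue, cur.model_id):
                    best[r.region_id] = h
                break
    return [best[k] for k in sorted(best)]


def length_distribution(
    hits: list[DomainHit],
    family_kind: dict[str, str],
    band_halfwidth: float = 0.35,
) -> pd.DataFrame:
    """Per-family domain-length summaries with outlier flags.

    Length is ``end - start + 1`` per hit.  Hits outside the reference band
    for their family's kind — centre 140 (single) or 271 (double), half
    width ``band_halfwidth`` as a fraction of the centre — are counted as
    outliers (partial matches or unusually large regions).
    """
    rows = [
        (h.model_id, h.protein_id, h.end - h.start + 1) for h in hits
    ]
    df = pd.DataFrame(rows, columns=["model_id", "protein_id", "length"])
    out = []
    for model_id, grp in df.groupby("model_id", sort=True):
        kind = family_kind.get(model_id, "single")
        centre = DOUBLE_LENGTH if kind == "double" else SINGLE_LENGTH
        lo, hi = centre * (1 - band_halfwidth), centre * (1 + band_halfwidth)
        lengths = grp["length"].to_numpy()
        outliers = grp.loc[(grp["length"] < lo) | (grp["length"] > hi), "protein_id"]
        out.append(
            {
                "model_id": model_id,
                "kind": kind,
                "n": len(lengths),
                "median": float(np.median(lengths)),
                "q1": float(np.percentile(lengths, 25)),
                "q3": float(np.percentile(lengths, 75)),
                "band_low": lo,
                "band_high": hi,
                "n_outliers": int(len(outliers)),
                "outliers": ",".join(outliers),
            }
        )
    return pd.DataFrame(out)


def coverage_table(
    hits: list[DomainHit],
    regions: list[ExtracellularRegion],
) -> tuple[list[CoverageRecord], pd.DataFrame, int]:
    """Coverage of extracellular regions by their domain hits.

    Each hit is assigned to the region enclosing it (same protein,
    overlapping coordinates); the domain span is clamped to the region
    bounds, and coverage is domain length over region length, binned at 10
    percentage points with the full-coverage case closed into the top bin.
    Returns the records, a bin-frequency table whose percentages sum to
    100, and the number of hits without an enclosing region (excluded).
    """
    by_protein: dict[str, list[ExtracellularRegion]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)

    records: list[CoverageRecord] = []
    n_orphans = 0
    for h in hits:
        region = None
        for r in by_protein.get(h.protein_id, []):
            if h.start <= r.end and h.end >= r.start:
                region = r
                break
        if region is None:
            n_orphans += 1
            continue
        dom_len = min(h.end, region.end) - max(h.start, region.start) + 1
        cov = dom_len / region.length
        b = min(int(cov * 100) // 10, 9)
        records.append(
            CoverageRecord(region.region_id, h.model_id, dom_len, region.length, cov, b)
        )

    counts = np.zeros(10, dtype=int)
    for rec in records:
        counts[rec.bin] += 1
    pct = 100.0 * counts / counts.sum() if counts.sum() else counts.astype(float)
    freq = pd.DataFrame(
        {
            "bin_low": np.arange(0, 100, 10),
            "bin_high": np.arange(10, 110, 10),
            "count": counts,
            "percent": pct,
        }
    )
    return records, freq, n_orphans


def abundance_ranking(
    hits: list[DomainHit],
    regions: list[ExtracellularRegion],
    family_of_model: dict[str, str] | None = None,
    superfamily_of_family: dict[str, str] | None = None,
    count_all_hits: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked domain counts per family and per superfamily.

    Counting is per region: each region contributes at most one count, to
    its best-scoring model (ties broken by lower E-value, then model id),
    unless ``count_all_hits`` is set.  Returns (per-family, per-superfamily)
    tables sorted by descending count.
    """
    family_of_model = family_of_model or {}
    by_region: dict[str, list[tuple[DomainHit, str]]] = {}
    by_protein: dict[str, list[ExtracellularRegion]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    for h in hits:
        for r in by_protein.get(h.protein_id, []):
            if h.start <= r.end and h.end >= r.start:
                by_region.setdefault(r.region_id, []).append((h, r.region_id))
                break

    counts: dict[str, int] = {}
    for region_id, rhits in by_region.items():
        if count_all_hits:
            chosen = [h for h, _ in rhits]
        else:
            chosen = [
                min(rhits, key=lambda hr: (hr[0].dom_evalue, hr[0].model_id))[0]
            ]
        for h in chosen:
            fam = family_of_model.get(h.model_id, h.model_id)
            counts[fam] = counts.get(fam, 0) + 1

    fam_df = (
        pd.DataFrame(sorted(counts.items()), columns=["family", "count"])
        .sort_values(["count", "family"], ascending=[False, True])
        .reset_index(drop=True)
    )
    if superfamily_of_family:
        fam_df["superfamily"] = fam_df["family"].map(
            lambda f: superfamily_of_family.get(f, "unassigned")
        )
        sf_df = (
            fam_df.groupby("superfamily", as_index=False)["count"].sum()
            .sort_values(["count", "superfamily"], ascending=[False, True])
            .reset_index(drop=True)
        )
    else:
        sf_df = pd.DataFrame(columns=["superfamily", "count"])
    return fam_df, sf_df


def phyletic_matrix(
    hits: list[DomainHit],
    protein_taxon: dict[str, str],
    taxon_proteins: dict[str, int],
    family_of_model: dict[str, str] | None = None,
    strain_to_species: dict[str, str] | None = None,
    species_to_clade: dict[str, str] | None = None,
    min_proteins: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence of each family across species, plus clade roll-up.

    A family is present in a species if *any* strain of that species has at
    least one hit.  Species whose total protein count (summed over strains)
    is not greater than ``min_proteins`` are dropped as incompletely
    sampled.  Proteins with unmapped taxa are gathered under
    "unclassified".  Returns the species x family 0/1 matrix (with a
    ``n_proteins`` column) and the any-descendant clade aggregation.
    """
    family_of_model = family_of_model or {}
    strain_to_species = strain_to_species or {}

    def species_of(taxon: str) -> str:
        return strain_to_species.get(taxon, taxon)

    species_proteins: dict[str, int] = {}
    for taxon, n in taxon_proteins.items():
        sp = species_of(taxon)
        species_proteins[sp] = species_proteins.get(sp, 0) + n

    presence: dict[str, set[str]] = {}
    for h in hits:
        taxon = protein_taxon.get(h.protein_id)
        sp = species_of(taxon) if taxon is not None else "unclassified"
        fam = family_of_model.get(h.model_id, h.model_id)
        presence.setdefault(sp, set()).add(fam)

    families = sorted({family_of_model.get(h.model_id, h.model_id) for h in hits})
    keep = sorted(
        sp for sp, n in species_proteins.items() if n > min_proteins
    )
    if "unclassified" in presence:
        keep.append("unclassified")
    rows = []
    for sp in keep:
        flags = {f: int(f in presence.get(sp, set())) for f in families}
        rows.append({"species": sp, "n_proteins": species_proteins.get(sp, 0), **flags})
    matrix = pd.DataFrame(rows, columns=["species", "n_proteins", *families])

    if species_to_clade:
        matrix["_clade"] = matrix["species"].map(
            lambda s: species_to_clade.get(s, "unclassified")
        )
        clade = matrix.groupby("_clade")[families].max().reset_index()
        clade = clade.rename(columns={"_clade": "clade"})
        matrix = matrix.drop(columns=["_clade"])
    else:
        clade = pd.DataFrame(columns=["clade", *families])
    return matrix, clade
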