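"""Taxonomic lineages and the genus-level read-assignment rule.

The pipeline deliberately limits taxonomic resolution to genus: 16S amplicon
reads rarely separate species reliably, so each read's classifier hits are
collapsed to a single genus, and reads whose hits span more than one genus are
left ``unassigned`` and contribute to no count.  Lineages are ingested from
the classifier scores CSV (tax_id, pipe-separated rank-prefixed lineage, rank,
name) and per-read hits from the taxonomy-annotated BAM tag (default ``YP``,
comma-separated taxon ids).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam

from .matrix import GenusCellMatrix

UNASSIGNED = "unassigned"
DEFAULT_TAXON_TAG = "YP"

#: Rank codes used in the lineage string, root -> leaf.
RANK_CODES = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

#: Probable reagent/environmental contaminants reported for low-biomass tumor
#: cohorts; an optional preset, never applied by default.
CONTAMINANT_PRESET = frozenset({"Patulibacter", "Pseudomonas", "Sphingomonas"})


@dataclass(frozen=True)
class TaxonEntry:
    name: str
    rank: str
    lineage: tuple[tuple[str, str], ...]  # (rank, name) ordered root -> leaf


@dataclass
class TaxonomyTable:
    """Mapping taxon id -> name, rank and full lineage."""

    entries: dict[int, TaxonEntry]

    def __getitem__(self, taxon_id: int) -> TaxonEntry:
        try:
            return self.entries[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon id {taxon_id}") from None

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TaxonomicHit:
    """All best-scoring taxon ids reported by the classifier for one read."""

    read_name: str
    taxon_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.taxon_ids:
            raise ValueError(f"hit for read {self.read_name!r} has no taxon ids")


def parse_lineage(lineage: str) -> tuple[tuple[str, str], ...]:
    """Parse ``k__Bacteria|...|g__Fusobacterium`` into ((rank, name), ...)."""
    out = []
    seen_ranks = set()
    for element in lineage.split("|"):
        code, _, name = element.partition("__")
        if code not in RANK_CODES or not name:
            raise ValueError(f"malformed lineage element {element!r} in {lineage!r}")
        rank = RANK_CODES[code]
        if rank in seen_ranks:
            raise ValueError(f"repeated rank {rank!r} in lineage {lineage!r}")
        seen_ranks.add(rank)
        out.append((rank, name))
    return tuple(out)


def format_lineage(lineage: Iterable[tuple[str, str]]) -> str:
    codes = {v: k for k, v in RANK_CODES.items()}
    return "|".join(f"{codes[rank]}__{name}" for rank, name in lineage)


def read_taxonomy_table(scores_csv: str | Path) -> TaxonomyTable:
    """Load the taxonomy table from the classifier scores CSV.

    Expected columns: ``tax_id``, ``taxonomy`` (pipe-separated rank-prefixed
    lineage), ``type`` (the entry's own rank), ``name``.
    """
    frame = pd.read_csv(scores_csv)
    required = {"tax_id", "taxonomy", "type", "name"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"scores CSV missing columns: {sorted(missing)}")
    entries = {}
    for row in frame.itertuples(index=False):
        entries[int(row.tax_id)] = TaxonEntry(
            name=str(row.name),
            rank=str(row.type),
            lineage=parse_lineage(str(row.taxonomy)),
        )
    return TaxonomyTable(entries)


def read_taxonomic_hits(
    path: str | Path, taxon_tag: str = DEFAULT_TAXON_TAG
) -> Iterator[TaxonomicHit]:
    """Stream per-read hits from a taxonomy-annotated SAM/BAM.

    Reads without the taxon tag are skipped (the classifier left them
    unclassified).
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.has_tag(taxon_tag):
                continue
            raw = str(aln.get_tag(taxon_tag))
            ids = tuple(int(tok) for tok in raw.split(",") if tok)
            if ids:
                yield TaxonomicHit(read_name=aln.query_name, taxon_ids=ids)


def genus_of(taxon_id: int, table: TaxonomyTable) -> str | None:
    """The genus-rank name in the lineage of taxon_id, or None if absent."""
    entry = table[taxon_id]
    for rank, name in entry.lineage:
        if rank == "genus":
            return name
    return None


def assign_read_genus(hit: TaxonomicHit, table: TaxonomyTable) -> str:
    """Collapse a read's hits to one genus, or ``unassigned``.

    The rule is conservative: the read is assigned only when *every* hit
    resolves (via :func:`genus_of`) to the same single genus.  Hits spanning
    multiple genera, or carrying only above-genus ranks, are unassigned and
    never counted.  Permutation-invariant in the hit's taxon ids.
    """
    genera = {genus_of(t, table) for t in hit.taxon_ids}
    if len(genera) == 1:
        (genus,) = genera
        if genus is not None:
            return genus
    return UNASSIGNED


def genus_calls(
    hits: Iterable[TaxonomicHit], table: TaxonomyTable
) -> dict[str, str]:
    """Per-read genus calls keyed by read name."""
    return {hit.read_name: assign_read_genus(hit, table) for hit in hits}


def apply_denylist(
    matrix: GenusCellMatrix, denylist: Iterable[str]
) -> GenusCellMatrix:
    """Remove the named genus columns (and their UMI sets) from a matrix.

    Cells are retained even when all their counts were in denylisted genera;
    a denylisted genus absent from the matrix is a no-op.  Idempotent, and
    commutes with matrix merging.
    """
    return matrix.without_genera(denylist)
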