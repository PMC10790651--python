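"""Readers and writers for the external formats the pipeline touches.

Dialects follow the CellRanger / GATK-PathSeq ecosystem: barcode whitelists are
one barcode per line (optionally gzipped, detected by magic bytes, never by
extension); alignments carry the corrected cell-barcode and UMI in the ``CB``
and ``UB`` tags; gene sets are tab-separated GMT.  Barcodes are compared
verbatim — the ``-1`` GEM-well suffix is never stripped, because whitelist and
BAM tags originate from the same upstream run.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
import pysam

from .matrix import GenusCellMatrix

DEFAULT_CB_TAG = "CB"
DEFAULT_UMI_TAG = "UB"

GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class BarcodeWhitelist:
    """The set of cell barcodes accepted as real cells."""

    barcodes: frozenset[str]

    def __contains__(self, barcode: object) -> bool:
        return barcode in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass(frozen=True)
class ReadRecord:
    """One alignment line, reduced to the fields the pipeline consumes."""

    read_name: str
    is_host_mapped: bool
    is_secondary_or_supplementary: bool = False
    cell_barcode: str | None = None
    umi: str | None = None
    sequence: str | None = None
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.read_name:
            raise ValueError("read_name must be non-empty")
        if (
            self.sequence is not None
            and self.qualities is not None
            and len(self.sequence) != len(self.qualities)
        ):
            raise ValueError(
                f"qualities length {len(self.qualities)} != sequence length "
                f"{len(self.sequence)} for read {self.read_name}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets with per-set gene order preserved (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def _open_text(path: str | Path) -> _io.TextIOBase:
    """Open a possibly-gzipped text file, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# barcode whitelist
# ---------------------------------------------------------------------------


def read_barcode_whitelist(path: str | Path) -> BarcodeWhitelist:
    """Read a barcode whitelist (one barcode per line, plain or gzipped).

    Raises
    ------
    ValueError
        If the file is empty or contains a duplicate barcode.
    """
    seen: set[str] = set()
    with _open_text(path) as fh:
        for line in fh:
            token = line.strip()
            if not token:
                continue
            if token in seen:
                raise ValueError(f"duplicate barcode in whitelist: {token!r}")
            seen.add(token)
    if not seen:
        raise ValueError(f"empty whitelist: {path}")
    return BarcodeWhitelist(frozenset(seen))


def write_barcode_whitelist(
    whitelist: BarcodeWhitelist | set[str], path: str | Path, compress: bool = True
) -> None:
    barcodes = sorted(
        whitelist.barcodes if isinstance(whitelist, BarcodeWhitelist) else whitelist
    )
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        for bc in barcodes:
            fh.write(bc + "\n")


# ---------------------------------------------------------------------------
# tagged alignments
# ---------------------------------------------------------------------------


def read_tagged_alignments(
    path: str | Path,
    cb_tag: str = DEFAULT_CB_TAG,
    umi_tag: str = DEFAULT_UMI_TAG,
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a SAM/BAM file (single pass, order-preserving).

    Host-mapped status comes from the unmapped flag; missing CB/UB tags yield
    absent fields rather than errors.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            quals = aln.query_qualities
            yield ReadRecord(
                read_name=aln.query_name,
                is_host_mapped=not aln.is_unmapped,
                is_secondary_or_supplementary=aln.is_secondary or aln.is_supplementary,
                cell_barcode=aln.get_tag(cb_tag) if aln.has_tag(cb_tag) else None,
                umi=aln.get_tag(umi_tag) if aln.has_tag(umi_tag) else None,
                sequence=aln.query_sequence,
                qualities=tuple(quals) if quals is not None else None,
            )


# ---------------------------------------------------------------------------
# genus x cell matrix CSV + UMI-set sidecar
# ---------------------------------------------------------------------------


def write_genus_matrix(
    matrix: GenusCellMatrix, csv_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write the integer count CSV and, optionally, the UMI-set sidecar TSV.

    The CSV has cell ids as the row index and genus names as columns in
    lexicographic order. The sidecar holds one (cell_id, genus, umi) row per
    distinct UMI so the matrix can be merged losslessly after a round-trip.
    """
    matrix.to_frame().to_csv(csv_path)
    if sidecar_path is not None:
        with open(sidecar_path, "wt") as fh:
            fh.write("cell_id\tgenus\tumi\n")
            for cell, genus, umis in matrix.iter_entries():
                for umi in sorted(umis):
                    fh.write(f"{cell}\t{genus}\t{umi}\n")


def read_genus_matrix(
    csv_path: str | Path, sidecar_path: str | Path, source: str | None = None
) -> GenusCellMatrix:
    """Rebuild a full GenusCellMatrix from count CSV + UMI-set sidecar.

    The sidecar is mandatory: bare counts cannot be deduplicated against other
    matrices, so merging refuses them (see :mod:`scbacteria.merge`).

    Raises
    ------
    ValueError
        On malformed headers, negative or non-integer counts, or counts that
        disagree with the sidecar's distinct-UMI cardinalities.
    """
    counts = read_genus_counts(csv_path)
    matrix = GenusCellMatrix(source=source)
    for cell in counts.index:
        matrix.add_cell(str(cell))
    sidecar = pd.read_csv(sidecar_path, sep="\t", dtype=str)
    if list(sidecar.columns) != ["cell_id", "genus", "umi"]:
        raise ValueError(
            f"malformed sidecar header {list(sidecar.columns)} in {sidecar_path}"
        )
    for row in sidecar.itertuples(index=False):
        matrix.add(row.cell_id, row.genus, row.umi)
    for cell in matrix.cell_ids:
        for genus in matrix.genera:
            expected = int(counts.at[cell, genus]) if genus in counts.columns else 0
            if matrix.count(cell, genus) != expected:
                raise ValueError(
                    f"sidecar UMI set for ({cell}, {genus}) has "
                    f"{matrix.count(cell, genus)} UMIs but CSV says {expected}"
                )
    return matrix


def read_genus_counts(csv_path: str | Path) -> pd.DataFrame:
    """Read the integer count CSV alone (no merging possible from this)."""
    frame = pd.read_csv(csv_path, index_col=0)
    if frame.index.name != "cell_id":
        raise ValueError(
            f"malformed matrix CSV header: first column is "
            f"{frame.index.name!r}, expected 'cell_id'"
        )
    for col in frame.columns:
        values = frame[col]
        if not pd.api.types.is_integer_dtype(values):
            raise ValueError(f"non-integer counts in column {col!r}")
        if (values < 0).any():
            raise ValueError(f"negative count in column {col!r}")
    frame.index = frame.index.astype(str)
    return frame.astype(int)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# sample manifest
# ---------------------------------------------------------------------------


def read_sample_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest CSV with columns sample, gex, microbial."""
    manifest = pd.read_csv(path, dtype=str)
    required = ["sample", "gex", "microbial"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if manifest["sample"].duplicated().any():
        dupes = manifest.loc[manifest["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample names in manifest: {dupes}")
    return manifest[required]
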