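"""Pipeline core: candidate selection, read trimming, and UMI accumulation.

Two library types feed the quantifier.  The gene-expression (GEX) library
contributes reads that failed to map to the host genome but carry a corrected
cell barcode and UMI; the 16S-enrichment (amplicon) library contributes every
barcoded+UMI-tagged read regardless of host-mapping status, because that
library is 16S-targeted and any host alignment there is incidental.  UMIs are
compared by exact sequence — no error-aware network collapsing — so distinct-
UMI counts are reproducible and conservative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .io import BarcodeWhitelist, ReadRecord
from .matrix import GenusCellMatrix
from .taxonomy import UNASSIGNED

Library = Literal["gex", "amplicon"]

#: Minimum 3'-end overlap (bases) for a partial adapter match to be clipped.
MIN_ADAPTER_OVERLAP = 10


@dataclass(frozen=True)
class TrimParams:
    """Quality/adapter trimming operators and thresholds.

    Defaults are the standard single-end settings for the amplicon Read-1
    path: LEADING:3 TRAILING:3 SLIDINGWINDOW:4:15 MINLEN:36 HEADCROP:15.
    Operators apply per read in the order: adapter clip,
    HEADCROP, LEADING, TRAILING, SLIDINGWINDOW, MINLEN.
    """

    adapter_sequences: tuple[str, ...] = ()
    leading_q: int = 3
    trailing_q: int = 3
    window_len: int = 4
    window_q: int = 15
    min_len: int = 36
    headcrop: int = 15

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        for name in ("leading_q", "trailing_q", "window_q", "min_len", "headcrop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CandidateRead:
    """A read that passed filtering and can carry a bacterial UMI."""

    read_name: str
    cell_barcode: str
    umi: str
    library: Library


@dataclass(frozen=True)
class ValidationRecord:
    """One nonzero (cell, genus) entry with its bacteria-associated flag."""

    cell_id: str
    genus: str
    umi_count: int

    @property
    def is_bacteria_associated(self) -> bool:
        return self.umi_count >= 1


@dataclass(frozen=True)
class ReadLevelAnnotation:
    """Audit row for every classified candidate read (incl. unassigned)."""

    read_name: str
    cell_barcode: str
    umi: str
    genus: str
    library: Library


@dataclass
class ExtractionSummary:
    """Per-drop-reason tallies from candidate extraction."""

    total: int = 0
    kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.total += 1
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    def keep(self) -> None:
        self.total += 1
        self.kept += 1

    def to_dict(self) -> dict:
        return {"total": self.total, "kept": self.kept, "dropped": dict(self.dropped)}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def extract_candidates(
    alignments: Iterable[ReadRecord],
    whitelist: BarcodeWhitelist,
    library: Library,
) -> tuple[list[CandidateRead], ExtractionSummary]:
    """Select reads that can carry a cell-associated bacterial UMI.

    GEX library: keep reads that are unmapped to the host, carry a
    whitelisted cell barcode and a UMI, and are primary alignments.
    Amplicon library: same, except host-mapping status is ignored.
    Filtered reads are tallied by the first failing check
    (secondary, host_mapped, barcode, umi).
    """
    if library not in ("gex", "amplicon"):
        raise ValueError(f"unknown library {library!r}")
    candidates: list[CandidateRead] = []
    summary = ExtractionSummary()
    for rec in alignments:
        if rec.is_secondary_or_supplementary:
            summary.drop("secondary")
        elif library == "gex" and rec.is_host_mapped:
            summary.drop("host_mapped")
        elif rec.cell_barcode is None or rec.cell_barcode not in whitelist:
            summary.drop("barcode")
        elif rec.umi is None:
            summary.drop("umi")
        else:
            summary.keep()
            candidates.append(
                CandidateRead(
                    read_name=rec.read_name,
                    cell_barcode=rec.cell_barcode,
                    umi=rec.umi,
                    library=library,
                )
            )
    return candidates, summary


# ---------------------------------------------------------------------------
# quality trimming
# ---------------------------------------------------------------------------


def _adapter_cut(sequence: str, adapters: Sequence[str]) -> int:
    """Index at which to truncate for adapter contamination (len(seq) if none).

    Clips at the leftmost exact occurrence of any adapter anywhere in the
    read, or at a 3'-terminal match to an adapter prefix of >= 10 bases.
    A simplification of seed-and-extend adapter trimming; documented as such.
    """
    cut = len(sequence)
    for adapter in adapters:
        pos = sequence.find(adapter)
        if pos != -1:
            cut = min(cut, pos)
        max_overlap = min(len(adapter), len(sequence))
        for k in range(max_overlap, MIN_ADAPTER_OVERLAP - 1, -1):
            if sequence.endswith(adapter[:k]):
                cut = min(cut, len(sequence) - k)
                break
    return cut


def quality_trim(
    sequence: str,
    qualities: Sequence[int],
    params: TrimParams = TrimParams(),
) -> tuple[str, tuple[int, ...]] | None:
    """Apply adapter clipping and quality trimming to one read.

    Returns the trimmed (sequence, qualities) or None if the read is
    discarded by the minimum-length filter.  Output qualities always stay
    aligned to the output sequence, and trimming never lengthens a read.
    """
    if len(sequence) != len(qualities):
        raise ValueError(
            f"sequence length {len(sequence)} != qualities length {len(qualities)}"
        )
    quals = list(qualities)

    cut = _adapter_cut(sequence, params.adapter_sequences)
    sequence, quals = sequence[:cut], quals[:cut]

    sequence, quals = sequence[params.headcrop :], quals[params.headcrop :]

    start = 0
    while start < len(quals) and quals[start] < params.leading_q:
        start += 1
    sequence, quals = sequence[start:], quals[start:]

    end = len(quals)
    while end > 0 and quals[end - 1] < params.trailing_q:
        end -= 1
    sequence, quals = sequence[:end], quals[:end]

    # sliding window: cut at the first window whose mean quality drops below
    # the threshold, then trim remaining trailing bases below it
    w, wq = params.window_len, params.window_q
    for i in range(0, len(quals) - w + 1):
        if sum(quals[i : i + w]) < wq * w:
            sequence, quals = sequence[:i], quals[:i]
            end = len(quals)
            while end > 0 and quals[end - 1] < wq:
                end -= 1
            sequence, quals = sequence[:end], quals[:end]
            break

    if len(sequence) < params.min_len:
        return None
    return sequence, tuple(quals)


# ---------------------------------------------------------------------------
# UMI accumulation
# ---------------------------------------------------------------------------


def build_umi_matrix(
    candidates: Iterable[CandidateRead],
    genus_calls: Mapping[str, str],
    sample: str,
) -> tuple[GenusCellMatrix, list[ValidationRecord], list[ReadLevelAnnotation]]:
    """Accumulate genus x cell distinct-UMI sets from classified candidates.

    Cell ids are ``sample_barcode`` (underscore separator) so they join the
    host expression object after multi-sample merging.  Candidates without a
    genus call are unclassified and ignored; candidates called ``unassigned``
    appear in the read-level annotations but never in the matrix.
    """
    matrix = GenusCellMatrix(source=sample)
    annotations: list[ReadLevelAnnotation] = []
    library: Library | None = None
    for cand in candidates:
        call = genus_calls.get(cand.read_name)
        if call is None:
            continue
        library = cand.library
        annotations.append(
            ReadLevelAnnotation(
                read_name=cand.read_name,
                cell_barcode=cand.cell_barcode,
                umi=cand.umi,
                genus=call,
                library=cand.library,
            )
        )
        if call != UNASSIGNED:
            matrix.add(f"{sample}_{cand.cell_barcode}", call, cand.umi)
    if library is not None:
        matrix.source = f"{sample}.{library}"
    validations = [
        ValidationRecord(cell_id=c, genus=g, umi_count=len(umis))
        for c, g, umis in matrix.iter_entries()
        if umis
    ]
    return matrix, validations, annotations


def write_validation_csv(records: Sequence[ValidationRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("cell_id,genus,umi_count,bacteria_flag\n")
        for rec in records:
            fh.write(
                f"{rec.cell_id},{rec.genus},{rec.umi_count},"
                f"{str(rec.is_bacteria_associated).lower()}\n"
            )


def write_read_annotations(
    annotations: Sequence[ReadLevelAnnotation], path: str | Path
) -> None:
    with open(path, "wt") as fh:
        fh.write("read_name\tcell_barcode\tumi\tgenus\tlibrary\n")
        for ann in annotations:
            fh.write(
                f"{ann.read_name}\t{ann.cell_barcode}\t{ann.umi}\t"
                f"{ann.genus}\t{ann.library}\n"
            )


def write_candidate_fasta(
    candidates: Sequence[CandidateRead],
    sequences: Mapping[str, str],
    path: str | Path,
) -> None:
    """FASTA of candidate read sequences (functional analogue of the
    intermediate candidate-read file in the original pipeline; no byte
    compatibility claimed)."""
    with open(path, "wt") as fh:
        for cand in candidates:
            seq = sequences.get(cand.read_name)
            if seq:
                fh.write(f">{cand.read_name}\n{seq}\n")


def read_budget(n_cells: int, reads_per_cell: int) -> int:
    """Total sequencing reads required for a target per-cell depth.

    E.g. 4,000 captured cells at 20,000 reads per cell need 80 million reads.
    """
    if n_cells < 0 or reads_per_cell < 0:
        raise ValueError("n_cells and reads_per_cell must be >= 0")
    return n_cells * reads_per_cell
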