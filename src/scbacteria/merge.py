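"""Merging the GEX- and amplicon-library matrices with UMI deduplication.

Both libraries derive from the same droplet emulsion, so an identical
(cell barcode, genus, UMI sequence) observation in the two libraries is one
captured molecule and must be counted once.  The merge therefore unions the
per-(cell, genus) UMI-sequence sets and re-derives counts — which is why the
UMI-set sidecar is a hard requirement: bare count CSVs cannot be
deduplicated and are refused.

Multiple samples can be merged at once; cross-sample deduplication never
occurs because cell ids carry sample prefixes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .io import write_genus_matrix
from .matrix import GenusCellMatrix

#: Default file name of the merged bacteria UMI matrix.
MERGED_MATRIX_NAME = "csv_novami.csv"


class MergedMatrix(GenusCellMatrix):
    """A GenusCellMatrix that also records which source libraries saw each
    (cell, genus, UMI) observation."""

    def __init__(self, source: str | None = None) -> None:
        super().__init__(source=source)
        self.provenance: dict[tuple[str, str, str], set[str]] = {}

    def add_from(self, cell_id: str, genus: str, umi: str, source: str) -> None:
        self.add(cell_id, genus, umi)
        self.provenance.setdefault((cell_id, genus, umi), set()).add(source)

    def _copy_extra_state(self, out: GenusCellMatrix, dropped: set[str]) -> None:
        if isinstance(out, MergedMatrix):
            out.provenance = {
                key: set(srcs)
                for key, srcs in self.provenance.items()
                if key[1] not in dropped
            }


def merge_matrices(
    matrices: Sequence[GenusCellMatrix],
    sources: Sequence[str] | None = None,
) -> MergedMatrix:
    """Union per-(cell, genus) UMI sets across matrices, counting each
    (cell, genus, UMI) once regardless of how many libraries observed it.

    Commutative, associative and idempotent; the merged count is at most the
    sum of input counts, with equality iff no observation overlaps.
    """
    if not matrices:
        raise ValueError("nothing to merge")
    if sources is None:
        sources = [m.source or f"matrix{i}" for i, m in enumerate(matrices)]
    if len(sources) != len(matrices):
        raise ValueError("sources must match matrices one-to-one")
    merged = MergedMatrix(source="+".join(sources))
    for matrix, src in zip(matrices, sources):
        for cell in matrix.cell_ids:
            merged.add_cell(cell)
        for cell, genus, umis in matrix.iter_entries():
            if isinstance(matrix, MergedMatrix):
                for umi in umis:
                    for origin in matrix.provenance.get((cell, genus, umi), {src}):
                        merged.add_from(cell, genus, umi, origin)
            else:
                for umi in umis:
                    merged.add_from(cell, genus, umi, src)
    return merged


def write_merged_matrix(merged: MergedMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write the merged count CSV, UMI-set sidecar and provenance TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / MERGED_MATRIX_NAME
    sidecar_path = outdir / (MERGED_MATRIX_NAME + ".umis.tsv")
    prov_path = outdir / (MERGED_MATRIX_NAME + ".provenance.tsv")
    write_genus_matrix(merged, csv_path, sidecar_path)
    with open(prov_path, "wt") as fh:
        fh.write("cell_id\tgenus\tumi\tsources\n")
        for (cell, genus, umi), srcs in sorted(merged.provenance.items()):
            fh.write(f"{cell}\t{genus}\t{umi}\t{','.join(sorted(srcs))}\n")
    return {"matrix": csv_path, "sidecar": sidecar_path, "provenance": prov_path}
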