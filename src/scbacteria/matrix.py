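"""The genus x cell UMI-set container at the centre of the pipeline.

Counts are always *derived* from sets of distinct UMI sequences, never stored
independently, so deduplication is structural: inserting the same
(cell, genus, UMI) observation twice cannot change a count.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import pandas as pd


class GenusCellMatrix:
    """Per-(cell, genus) sets of distinct UMI sequences.

    Cells are registered independently of observations so that a cell whose
    every count is later removed (e.g. by a contaminant denylist) is retained
    with zero totals rather than silently dropped.

    Parameters
    ----------
    source:
        Optional label naming the library/sample this matrix was built from
        (e.g. ``"SampleX.gex"``); carried into merge provenance.
    """

    def __init__(self, source: str | None = None) -> None:
        self._umi_sets: dict[tuple[str, str], set[str]] = {}
        self._cells: set[str] = set()
        self.source = source

    # -- construction -----------------------------------------------------

    def add(self, cell_id: str, genus: str, umi: str) -> None:
        """Record one observation of a UMI for (cell_id, genus)."""
        self._cells.add(cell_id)
        self._umi_sets.setdefault((cell_id, genus), set()).add(umi)

    def add_cell(self, cell_id: str) -> None:
        """Register a cell with no observations (all-zero row)."""
        self._cells.add(cell_id)

    # -- views ------------------------------------------------------------

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self._cells)

    @property
    def genera(self) -> list[str]:
        return sorted({g for (_, g) in self._umi_sets})

    def umi_set(self, cell_id: str, genus: str) -> frozenset[str]:
        return frozenset(self._umi_sets.get((cell_id, genus), frozenset()))

    def count(self, cell_id: str, genus: str) -> int:
        return len(self._umi_sets.get((cell_id, genus), ()))

    def iter_entries(self) -> Iterator[tuple[str, str, frozenset[str]]]:
        for (c, g), umis in sorted(self._umi_sets.items()):
            yield c, g, frozenset(umis)

    def total_umis(self) -> int:
        """Sum of distinct-UMI counts over all (cell, genus) pairs."""
        return sum(len(s) for s in self._umi_sets.values())

    def to_frame(self) -> pd.DataFrame:
        """Integer count matrix: rows cell ids, columns genera (lexicographic)."""
        frame = pd.DataFrame(0, index=self.cell_ids, columns=self.genera, dtype=int)
        for (c, g), umis in self._umi_sets.items():
            frame.at[c, g] = len(umis)
        frame.index.name = "cell_id"
        return frame

    # -- transforms -------------------------------------------------------

    def without_genera(self, genera: Iterable[str]) -> "GenusCellMatrix":
        """A copy with the named genus columns (and their UMI sets) removed.

        Cells are retained even when all their observations are removed.
        """
        drop = set(genera)
        out = type(self)(source=self.source)
        out._cells = set(self._cells)
        for (c, g), umis in self._umi_sets.items():
            if g not in drop:
                out._umi_sets[(c, g)] = set(umis)
        self._copy_extra_state(out, drop)
        return out

    def _copy_extra_state(self, out: "GenusCellMatrix", dropped: set[str]) -> None:
        """Hook for subclasses carrying extra per-observation state."""

    def copy(self) -> "GenusCellMatrix":
        return self.without_genera(())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenusCellMatrix):
            return NotImplemented
        return (
            self._cells == other._cells
            and {k: set(v) for k, v in self._umi_sets.items() if v}
            == {k: set(v) for k, v in other._umi_sets.items() if v}
        )

    def __repr__(self) -> str:
        return (
            f"GenusCellMatrix({len(self._cells)} cells x {len(self.genera)} genera, "
            f"{self.total_umis()} UMIs)"
        )
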