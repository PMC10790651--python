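import numpy as np
import pytest

from scbacteria.matrix import GenusCellMatrix
from scbacteria.simulate import build_toy_taxonomy
from scbacteria.taxonomy import TaxonomyTable, read_taxonomy_table


@pytest.fixture(scope="session")
def toy_taxonomy(tmp_path_factory) -> tuple[TaxonomyTable, dict[str, list[int]]]:
    """A 5-genus, 10-species taxonomy loaded through the scores-CSV reader."""
    genera = ["Fusobacterium", "Treponema", "Prevotella", "Pseudomonas", "Selenomonas"]
    scores, genus_ids = build_toy_taxonomy(genera, species_per_genus=2)
    path = tmp_path_factory.mktemp("tax") / "scores.csv"
    scores.to_csv(path, index=False)
    return read_taxonomy_table(path), genus_ids


def random_matrix(rng: np.random.Generator, n_cells=6, n_genera=3,
                  umi_pool=20, source=None) -> GenusCellMatrix:
    """A small random GenusCellMatrix drawing UMIs from a shared pool so that
    different matrices overlap."""
    genera = [f"Genus{g}" for g in range(n_genera)]
    umis = [f"UMI{u:03d}" for u in range(umi_pool)]
    m = GenusCellMatrix(source=source)
    for c in range(n_cells):
        cell = f"s_CELL{c}"
        m.add_cell(cell)
        for g in genera:
            for u in rng.choice(umi_pool, size=rng.integers(0, 4), replace=False):
                m.add(cell, g, umis[u])
    return m
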