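"""Condition host transcriptome analysis on per-cell bacterial status.

Simulates 300 cells in which Fusobacterium-infected cells up-regulate 10
signal genes two-fold, runs the full pipeline, labels cells bacteria-positive
(>= 1 UMI here; the package default is >= 4) or bacteria-negative, then runs
Wilcoxon differential expression and preranked GSEA on the resulting ranking.
"""

import tempfile
from pathlib import Path

import pandas as pd

from scbacteria.analysis import (
    classify_cells,
    differential_expression,
    load_expression,
    normalize_expression,
    preranked_gsea,
    volcano_table,
)
from scbacteria.io import GeneSetCollection, read_genus_matrix
from scbacteria.pipeline import run_annotate, run_merge, run_quant
from scbacteria.simulate import SimulationConfig, TaxonConfig, simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    config = SimulationConfig(
        seed=3, n_cells=300, n_genes=300, n_signal_genes=10, signal_log2fc=1.0,
        taxa=(TaxonConfig(genus="Fusobacterium", infected_fraction=0.4),),
    )
    ds = simulate_dataset(config, tmp / "sim")

    gex = run_quant("gex", ds.gex_alignments, ds.whitelist, ds.gex_hits,
                    ds.scores_csv, "sim", tmp / "out")
    amp = run_quant("amplicon", ds.amplicon_alignments, ds.whitelist,
                    ds.amplicon_hits, ds.scores_csv, "sim", tmp / "out")
    run_merge([(gex["matrix"], gex["sidecar"]), (amp["matrix"], amp["sidecar"])],
              tmp / "merge")
    ann = run_annotate(tmp / "merge", ds.expression_dir, "sim", tmp / "ann")

    annotations = pd.read_csv(ann["annotations"], index_col=0)
    labels = classify_cells(annotations, taxon="Fusobacterium", pos_threshold=1)
    print(labels.value_counts(dropna=False).to_string())

    adata = normalize_expression(load_expression(ds.expression_dir, "sim"))
    de = differential_expression(adata, labels, min_pct=0.1)
    print("\ntop differentially expressed genes:")
    print(volcano_table(de).head(5).round(3).to_string())

    sets = GeneSetCollection({
        "SIGNAL_GENES": [f"GENE{j:04d}" for j in range(10)],
        "RANDOM_GENES": [f"GENE{j:04d}" for j in range(200, 220)],
    })
    results = preranked_gsea(de["log2_fold_change"], sets, n_perm=500, seed=7)
    print("\ngene-set enrichment:")
    for r in results:
        print(f"  {r.set_name:14s} ES={r.enrichment_score:+.3f} "
              f"NES={r.normalized_enrichment_score:+.2f} p={r.p_value:.4f}")
# The implanted signal genes dominate the top of the DE table (log2FC near
# the configured 1.0) and their set scores the maximal positive ES; the
# random set, sitting in the unchanged bulk below the signal genes, drifts
# mildly negative — rank-based enrichment is relative, not absolute.
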