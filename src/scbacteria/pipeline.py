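"""Stage orchestration: file-driven pipeline steps with run logging.

Stages communicate only via files so users can substitute real upstream
outputs (aligner BAMs, classifier results) for any simulated input; the
package never invokes those external tools itself.  Each stage writes its
outputs plus a ``<stage>.done.json`` marker holding a parameter hash; rerunning
a completed stage with identical parameters is a no-op unless forced.
Structured JSON-line run logs record per-stage record counts (reads in, kept,
dropped by reason; cells; genera) because troubleshooting hinges on where
reads are lost.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .analysis import (
    attach_bacteria_metadata,
    classify_cells,
    differential_expression,
    gsea_table,
    load_expression,
    normalize_expression,
    preranked_gsea,
    volcano_table,
)
from .io import (
    read_barcode_whitelist,
    read_gene_sets,
    read_genus_matrix,
    read_tagged_alignments,
    write_genus_matrix,
)
from .merge import MERGED_MATRIX_NAME, merge_matrices, write_merged_matrix
from .quant import (
    TrimParams,
    build_umi_matrix,
    extract_candidates,
    quality_trim,
    write_read_annotations,
    write_validation_csv,
)
from .taxonomy import (
    apply_denylist,
    genus_calls,
    read_taxonomic_hits,
    read_taxonomy_table,
)


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is missing; names the stage to run first."""


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _log(outdir: Path, stage: str, payload: dict) -> None:
    entry = {
        "stage": stage,
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "version": __version__,
        **payload,
    }
    with open(outdir / "run_log.jsonl", "at") as fh:
        fh.write(json.dumps(entry) + "\n")


def _stage_done(outdir: Path, stage: str, params: dict, force: bool) -> bool:
    marker = outdir / f"{stage}.done.json"
    if force or not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("hash") == _params_hash(params)
    except (json.JSONDecodeError, OSError):
        return False


def _mark_done(outdir: Path, stage: str, params: dict) -> None:
    (outdir / f"{stage}.done.json").write_text(
        json.dumps({"hash": _params_hash(params), "params": params}, default=str)
    )


def _require(path: Path, producer: str) -> Path:
    if not Path(path).exists():
        raise MissingArtifactError(
            f"missing {path}; run the '{producer}' stage first"
        )
    return Path(path)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_quant(
    library: str,
    alignments: str | Path,
    whitelist: str | Path,
    hits: str | Path,
    scores_csv: str | Path,
    sample: str,
    outdir: str | Path,
    cb_tag: str = "CB",
    umi_tag: str = "UB",
    taxon_tag: str = "YP",
    trim: TrimParams | None = None,
    force: bool = False,
) -> dict[str, Path]:
    """Quantify one library into a genus x cell matrix with sidecars.

    For the amplicon library, reads whose sequence fails quality trimming are
    excluded before the classification join (pass ``trim=TrimParams()`` to
    enable; in a real run trimming gates what reaches the classifier, so
    already-classified hits for surviving reads are the expected input).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {
        "stage": f"{library}-quant", "alignments": alignments, "sample": sample,
        "cb_tag": cb_tag, "umi_tag": umi_tag, "taxon_tag": taxon_tag,
        "trim": dataclasses.asdict(trim) if trim else None,
    }
    stage = f"{sample}.{library}-quant"
    prefix = outdir / f"{sample}.{library}"
    outputs = {
        "matrix": Path(f"{prefix}.genus.csv"),
        "sidecar": Path(f"{prefix}.genus.umis.tsv"),
        "validation": Path(f"{prefix}.validate.csv"),
        "annotations": Path(f"{prefix}.readnamepath.tsv"),
        "summary": Path(f"{prefix}.summary.json"),
    }
    if _stage_done(outdir, stage, params, force) and all(
        p.exists() for p in outputs.values()
    ):
        return outputs

    wl = read_barcode_whitelist(_require(Path(whitelist), "upstream inputs"))
    records = list(
        read_tagged_alignments(
            _require(Path(alignments), "upstream inputs"), cb_tag, umi_tag
        )
    )
    candidates, summary = extract_candidates(records, wl, library)

    if trim is not None:
        sequences = {
            r.read_name: (r.sequence, r.qualities)
            for r in records
            if r.sequence is not None and r.qualities is not None
        }
        survivors = set()
        for cand in candidates:
            seq_q = sequences.get(cand.read_name)
            if seq_q is None or quality_trim(seq_q[0], seq_q[1], trim) is not None:
                survivors.add(cand.read_name)
        n_trimmed_away = sum(c.read_name not in survivors for c in candidates)
        candidates = [c for c in candidates if c.read_name in survivors]
        summary.dropped["trim"] = n_trimmed_away
        summary.kept -= n_trimmed_away

    table = read_taxonomy_table(_require(Path(scores_csv), "upstream inputs"))
    calls = genus_calls(
        read_taxonomic_hits(_require(Path(hits), "upstream inputs"), taxon_tag),
        table,
    )
    matrix, validations, annotations = build_umi_matrix(candidates, calls, sample)

    write_genus_matrix(matrix, outputs["matrix"], outputs["sidecar"])
    write_validation_csv(validations, outputs["validation"])
    write_read_annotations(annotations, outputs["annotations"])
    summary.write_json(outputs["summary"])
    _log(outdir, stage, {
        **summary.to_dict(),
        "cells": len(matrix.cell_ids), "genera": len(matrix.genera),
    })
    _mark_done(outdir, stage, params)
    return outputs


def run_merge(
    matrix_paths: Sequence[tuple[str | Path, str | Path]],
    outdir: str | Path,
    sources: Sequence[str] | None = None,
    force: bool = False,
) -> dict[str, Path]:
    """Merge quantified matrices (CSV + mandatory UMI-set sidecar pairs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {"matrices": [str(p) for p, _ in matrix_paths], "sources": sources}
    outputs = {
        "matrix": outdir / MERGED_MATRIX_NAME,
        "sidecar": outdir / (MERGED_MATRIX_NAME + ".umis.tsv"),
        "provenance": outdir / (MERGED_MATRIX_NAME + ".provenance.tsv"),
    }
    if _stage_done(outdir, "merge", params, force) and all(
        p.exists() for p in outputs.values()
    ):
        return outputs
    matrices = [
        read_genus_matrix(
            _require(Path(csv), "gex-quant/amplicon-quant"),
            _require(Path(sidecar), "gex-quant/amplicon-quant"),
            source=Path(csv).stem,
        )
        for csv, sidecar in matrix_paths
    ]
    merged = merge_matrices(matrices, sources)
    write_merged_matrix(merged, outdir)
    _log(outdir, "merge", {
        "inputs": len(matrices), "cells": len(merged.cell_ids),
        "genera": len(merged.genera), "umis": merged.total_umis(),
    })
    _mark_done(outdir, "merge", params)
    return outputs


def run_annotate(
    merged_dir: str | Path,
    expression_dir: str | Path,
    sample: str | None,
    outdir: str | Path,
    denylist: Sequence[str] = (),
    force: bool = False,
) -> dict[str, Path]:
    """Attach bacterial metadata to the expression cell universe."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {"merged": str(merged_dir), "expression": str(expression_dir),
              "sample": sample, "denylist": sorted(denylist)}
    outputs = {"annotations": outdir / "cell_annotations.csv"}
    if _stage_done(outdir, "annotate", params, force) and outputs["annotations"].exists():
        return outputs
    merged_dir = Path(merged_dir)
    merged = read_genus_matrix(
        _require(merged_dir / MERGED_MATRIX_NAME, "merge"),
        _require(merged_dir / (MERGED_MATRIX_NAME + ".umis.tsv"), "merge"),
    )
    if denylist:
        merged = apply_denylist(merged, denylist)
    adata = load_expression(expression_dir, sample=sample)
    annotations = attach_bacteria_metadata(list(adata.obs_names), merged)
    dropped = len(set(merged.cell_ids) - set(annotations.index))
    annotations.to_csv(outputs["annotations"])
    _log(outdir, "annotate", {
        "cells": len(annotations), "matrix_cells_dropped": dropped,
        "genera": len(annotations.columns) - 1,
    })
    _mark_done(outdir, "annotate", params)
    return outputs


def run_analyze(
    annotations_csv: str | Path,
    expression_dir: str | Path,
    sample: str | None,
    outdir: str | Path,
    taxon: str,
    gene_sets: str | Path | None = None,
    pos_threshold: int = 4,
    min_pct: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    force: bool = False,
) -> dict[str, Path]:
    """Threshold grouping, differential expression and preranked GSEA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {"annotations": str(annotations_csv), "taxon": taxon,
              "pos_threshold": pos_threshold, "min_pct": min_pct,
              "n_perm": n_perm, "seed": seed, "gene_sets": str(gene_sets)}
    outputs = {
        "labels": outdir / "cell_groups.csv",
        "de": outdir / "de_table.csv",
        "volcano": outdir / "volcano.tsv",
    }
    if gene_sets is not None:
        outputs["gsea"] = outdir / "gsea_table.csv"
    if _stage_done(outdir, "analyze", params, force) and all(
        p.exists() for p in outputs.values()
    ):
        return outputs
    annotations = pd.read_csv(
        _require(Path(annotations_csv), "annotate"), index_col=0
    )
    labels = classify_cells(annotations, taxon=taxon, pos_threshold=pos_threshold)
    labels.to_csv(outputs["labels"])
    adata = load_expression(expression_dir, sample=sample)
    normalize_expression(adata)
    de = differential_expression(adata, labels, min_pct=min_pct)
    de.to_csv(outputs["de"])
    volcano_table(de).to_csv(outputs["volcano"], sep="\t")
    payload = {
        "positive": int((labels == "Positive").sum()),
        "negative": int((labels == "Negative").sum()),
        "excluded": int(labels.isna().sum()),
        "genes_tested": len(de),
    }
    if gene_sets is not None:
        sets = read_gene_sets(gene_sets)
        ranking = de["log2_fold_change"]
        results = preranked_gsea(ranking, sets, n_perm=n_perm, seed=seed)
        gsea_table(results).to_csv(outputs["gsea"])
        payload["gene_sets"] = len(results)
    _log(outdir, "analyze", payload)
    _mark_done(outdir, "analyze", params)
    return outputs
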