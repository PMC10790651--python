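"""Bacteria-status-conditioned host transcriptome analysis.

Given the merged bacteria UMI matrix and a host expression matrix, this module
attaches per-cell bacterial metadata, splits cells into bacteria-positive /
bacteria-negative / excluded groups by a UMI threshold, tests per-gene
expression differences with a two-sided Wilcoxon rank-sum test, adjusts with
Benjamini-Hochberg, and scores gene sets with preranked GSEA (weighted
Kolmogorov-Smirnov running sum, permutation null).

Grouping follows the threshold rule: a cell is Positive when its UMI count for
the focal taxon reaches the threshold (default 4), Negative when it carries no
bacterial UMIs at all, and otherwise excluded (cells with 1..threshold-1 UMIs
are too ambiguous to call either way).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .matrix import GenusCellMatrix

POSITIVE = "Positive"
NEGATIVE = "Negative"

TOTAL_COLUMN = "Total"

#: Volcano-plot significance cutoffs used for reporting:
#: |log2 fold change| >= 0.58 (~1.5-fold) and -log10 p >= 1.301 (p <= 0.05).
VOLCANO_LFC_CUTOFF = 0.58
VOLCANO_NEGLOG10P_CUTOFF = 1.301

DEFAULT_SCALE_FACTOR = 1e4
DEFAULT_POS_THRESHOLD = 4
DEFAULT_MIN_PCT = 0.1


# ---------------------------------------------------------------------------
# metadata attachment and grouping
# ---------------------------------------------------------------------------


def attach_bacteria_metadata(
    cells: Sequence[str], merged: GenusCellMatrix
) -> pd.DataFrame:
    """Per-cell bacterial UMI counts aligned to the expression cell universe.

    Every expression-matrix cell gets a row; cells absent from the merged
    matrix get all-zero counts (missing is never NA).  Matrix cells absent
    from the expression data are dropped.  A ``Total`` column holds the row
    sum over genera.

    Raises
    ------
    ValueError
        If no cell id overlaps (a naming-convention mismatch).
    """
    cells = [str(c) for c in cells]
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate cell ids in expression data")
    counts = merged.to_frame()
    if len(counts.index) and not set(cells) & set(counts.index):
        raise ValueError(
            "no overlap between expression cells and bacteria matrix cells; "
            "check the sample_barcode naming convention"
        )
    annotations = counts.reindex(cells).fillna(0).astype(int)
    annotations.index.name = "cell_id"
    annotations[TOTAL_COLUMN] = annotations.sum(axis=1)
    return annotations


def classify_cells(
    annotations: pd.DataFrame,
    taxon: str = TOTAL_COLUMN,
    pos_threshold: int = DEFAULT_POS_THRESHOLD,
) -> pd.Series:
    """Label cells Positive / Negative / NA by bacterial UMI count.

    Positive: count for ``taxon`` (a genus column or "Total") >= threshold.
    Negative: total bacterial UMIs == 0.
    NA (pd.NA): everything else — excluded from group comparisons.

    Raising the threshold can only shrink the Positive set.
    """
    if pos_threshold < 1:
        raise ValueError("pos_threshold must be >= 1")
    if taxon not in annotations.columns:
        raise KeyError(f"taxon {taxon!r} not in annotations")
    taxon_counts = annotations[taxon]
    total = annotations[TOTAL_COLUMN]
    labels = pd.Series(pd.NA, index=annotations.index, dtype=object)
    labels[total == 0] = NEGATIVE
    labels[taxon_counts >= pos_threshold] = POSITIVE
    labels.name = "bacteria_group"
    return labels


# ---------------------------------------------------------------------------
# expression loading / normalization
# ---------------------------------------------------------------------------


def load_expression(mtx_dir: str | Path, sample: str | None = None):
    """Load a CellRanger-layout MTX directory into an AnnData (cells x genes).

    Accepts plain or gzipped matrix.mtx / features.tsv / barcodes.tsv (the
    features file may be 1- or 3-column).  When ``sample`` is given, cell
    names are prefixed ``sample_barcode`` to match the bacteria-matrix
    convention.
    """
    import anndata
    from scipy.io import mmread
    from scipy.sparse import csr_matrix

    mtx_dir = Path(mtx_dir)

    def find(stem: str) -> Path:
        for name in (stem, stem + ".gz"):
            if (mtx_dir / name).exists():
                return mtx_dir / name
        raise FileNotFoundError(f"no {stem}[.gz] in {mtx_dir}")

    matrix = csr_matrix(mmread(find("matrix.mtx"))).T  # stored genes x cells
    features = pd.read_csv(find("features.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(find("barcodes.tsv"), sep="\t", header=None)[0]
    adata = anndata.AnnData(
        X=matrix.astype(np.float32),
        obs=pd.DataFrame(index=barcodes.astype(str).tolist()),
        var=pd.DataFrame(index=features[0].astype(str).tolist()),
    )
    if sample is not None:
        adata.obs_names = [f"{sample}_{bc}" for bc in adata.obs_names]
    return adata


def normalize_expression(adata, scale_factor: float = DEFAULT_SCALE_FACTOR):
    """Log-normalize counts in place: per-cell scaling to ``scale_factor``
    total counts followed by log1p."""
    import scanpy as sc

    sc.pp.normalize_total(adata, target_sum=scale_factor)
    sc.pp.log1p(adata)
    return adata


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DEResult:
    gene: str
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    pct_pos: float
    pct_neg: float


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _expression_arrays(expression, labels: pd.Series):
    """Split a normalized expression container into positive/negative dense
    arrays (cells x genes) plus the gene index."""
    try:
        import anndata

        is_adata = isinstance(expression, anndata.AnnData)
    except ImportError:  # pragma: no cover
        is_adata = False
    if is_adata:
        obs_names = pd.Index(expression.obs_names)
        genes = pd.Index(expression.var_names)

        def rows(mask: np.ndarray) -> np.ndarray:
            X = expression.X[mask]
            return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)

    elif isinstance(expression, pd.DataFrame):
        # genes x cells orientation
        obs_names = pd.Index(expression.columns)
        genes = pd.Index(expression.index)

        def rows(mask: np.ndarray) -> np.ndarray:
            return expression.loc[:, obs_names[mask]].to_numpy().T

    else:
        raise TypeError("expression must be an AnnData or a genes x cells DataFrame")

    labels = labels.reindex(obs_names)
    pos_mask = (labels == POSITIVE).to_numpy()
    neg_mask = (labels == NEGATIVE).to_numpy()
    return rows(pos_mask), rows(neg_mask), genes


def differential_expression(
    expression,
    labels: pd.Series,
    min_pct: float = DEFAULT_MIN_PCT,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum test, Positive vs Negative cells.

    Parameters
    ----------
    expression:
        Normalized expression: an AnnData (cells x genes, log-normalized .X)
        or a genes x cells DataFrame.
    labels:
        Cell group labels from :func:`classify_cells`; NA cells are excluded
        and their expression never enters the test.
    min_pct:
        Only genes detected (value > 0) in at least this fraction of cells in
        one of the two groups are tested.

    Returns
    -------
    DataFrame indexed by gene with columns log2_fold_change, p_value,
    p_adjusted, pct_pos, pct_neg, sorted by ascending p-value.  The fold
    change is log2((mean expm1 expression in Positive + 1) /
    (mean in Negative + 1)); BH adjustment is over tested genes only.
    """
    pos, neg, genes = _expression_arrays(expression, labels)
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError(
            f"need >=2 cells per group, got {pos.shape[0]} Positive and "
            f"{neg.shape[0]} Negative"
        )
    pct_pos = (pos > 0).mean(axis=0)
    pct_neg = (neg > 0).mean(axis=0)
    tested = (pct_pos >= min_pct) | (pct_neg >= min_pct)

    mean_pos = np.expm1(pos).mean(axis=0)
    mean_neg = np.expm1(neg).mean(axis=0)
    log2fc = np.log2((mean_pos + 1.0) / (mean_neg + 1.0))

    p_values = np.ones(tested.sum())
    idx = np.flatnonzero(tested)
    for k, j in enumerate(idx):
        x, y = pos[:, j], neg[:, j]
        if np.ptp(np.concatenate([x, y])) == 0:
            p_values[k] = 1.0  # constant gene: no signal by construction
        else:
            p_values[k] = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="auto"
            ).pvalue
    result = pd.DataFrame(
        {
            "log2_fold_change": log2fc[idx],
            "p_value": p_values,
            "p_adjusted": bh_adjust(p_values),
            "pct_pos": pct_pos[idx],
            "pct_neg": pct_neg[idx],
        },
        index=genes[idx],
    )
    result.index.name = "gene"
    return result.sort_values("p_value", kind="stable")


def volcano_table(
    de: pd.DataFrame,
    lfc_cutoff: float = VOLCANO_LFC_CUTOFF,
    neglog10p_cutoff: float = VOLCANO_NEGLOG10P_CUTOFF,
) -> pd.DataFrame:
    """Add -log10 p and a significance flag at the volcano-plot cutoffs."""
    out = de.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    out["significant"] = (out["log2_fold_change"].abs() >= lfc_cutoff) & (
        out["neg_log10_p"] >= neglog10p_cutoff
    )
    return out


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    enrichment_score: float
    normalized_enrichment_score: float
    p_value: float
    leading_edge: tuple[str, ...]
    n_hits: int


def _running_sum_es(
    weights: np.ndarray, hit_mask: np.ndarray
) -> tuple[float, int]:
    """Signed maximum deviation of the weighted KS running sum and its
    position.  Hits step up by |weight| / sum(|hit weights|); misses step
    down by 1 / (N - Nh).  When every gene is a hit there are no misses and
    the miss decrement is 0."""
    n = weights.size
    n_hit = int(hit_mask.sum())
    hit_weights = np.abs(weights) * hit_mask
    total = hit_weights.sum()
    if total == 0:
        # all hit weights zero (flat ranking): fall back to equal increments
        hit_weights = hit_mask.astype(float)
        total = hit_weights.sum()
    miss_pen = 1.0 / (n - n_hit) if n > n_hit else 0.0
    steps = np.where(hit_mask, hit_weights / total, -miss_pen)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def preranked_gsea(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[GseaResult]:
    """Preranked gene-set enrichment with a weighted KS running sum.

    Parameters
    ----------
    ranking:
        Gene -> ranking value (e.g. average log2 fold change).  Sorted
        internally by descending value (ties broken by gene name for
        determinism); weight exponent 1 on |value|.
    sets:
        Gene sets; a set disjoint from the ranking is reported as untestable
        (NaN scores) rather than raising.
    n_perm:
        Gene-label permutations for the null; the two-sided permutation
        p-value uses +1 continuity, so the smallest attainable p is
        1 / (n_perm + 1).

    The normalized enrichment score divides ES by the mean |null ES| of
    matching sign.
    """
    if not np.all(np.isfinite(ranking.to_numpy(dtype=float))):
        raise ValueError("ranking values must be finite")
    order = sorted(ranking.index, key=lambda g: (-ranking[g], g))
    genes = np.array(order)
    values = ranking.loc[order].to_numpy(dtype=float)
    n = genes.size
    rng = np.random.default_rng(seed)

    results: list[GseaResult] = []
    for name in sets.sets:
        members = set(sets[name])
        hit_mask = np.isin(genes, list(members))
        n_hit = int(hit_mask.sum())
        if n_hit == 0:
            results.append(
                GseaResult(name, float("nan"), float("nan"), float("nan"), (), 0)
            )
            continue
        es, peak = _running_sum_es(values, hit_mask)
        if es >= 0:
            leading = tuple(genes[: peak + 1][hit_mask[: peak + 1]])
        else:
            leading = tuple(genes[peak:][hit_mask[peak:]])
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=n_hit, replace=False)] = True
            null_es[b], _ = _running_sum_es(values, perm_mask)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        nes = (
            es / np.mean(np.abs(same_sign)) if same_sign.size else float("nan")
        )
        p = (1.0 + np.sum(np.abs(null_es) >= abs(es))) / (n_perm + 1.0)
        results.append(GseaResult(name, es, float(nes), float(p), leading, n_hit))
    return results


def gsea_table(results: Sequence[GseaResult]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.enrichment_score for r in results],
            "nes": [r.normalized_enrichment_score for r in results],
            "p_value": [r.p_value for r in results],
            "n_hits": [r.n_hits for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
        }
    ).set_index("set_name")
    return frame
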