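"""Synthetic end-to-end fixtures with known ground truth.

The generator emulates the validation designs used to establish the method:
a dose-response design in which raising the infected fraction of cells (a
proxy for multiplicity of infection) raises the number of detectable
bacteria-positive cells; a nonadherent negative-control taxon whose reads are
purely ambient (no valid cell barcode) and must yield zero cell-associated
UMIs; and contaminant taxa for exercising the denylist.

Per-infected-cell bacterial UMI loads are negative-binomial, reflecting the
heavy-tailed loads seen in real data (a few cells with >100 bacterial
transcripts, many with one or none).  Classifier emulation writes per-read
taxon hits directly — no sequence-based classification is simulated — and a
misassignment probability routes reads through the multi-genus "unassigned"
path.

Infected-cell selection is rank-coupled: each cell draws one dedicated
uniform per taxon and the round(fraction * n) smallest are infected, so under
a fixed seed a larger infected fraction infects a superset of cells and group
sizes are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .io import write_barcode_whitelist
from .matrix import GenusCellMatrix
from .taxonomy import format_lineage

_BASES = np.array(list("ACGT"))

_PURPOSES = {
    "barcodes": 0,
    "infection": 1,
    "umis": 2,
    "reads": 3,
    "ambient": 4,
    "expression": 5,
    "host": 6,
}


@dataclass(frozen=True)
class TaxonConfig:
    """Simulation parameters for one bacterial genus.

    infected_fraction: fraction of cells truly carrying this genus.
    mean_umis / dispersion: negative-binomial distinct-UMI load per infected
    cell (dispersion is the NB size parameter; smaller = heavier tail).
    ambient_read_rate: expected number of ambient reads (no valid barcode)
    for this genus per dataset — a nonadherent taxon has infected_fraction 0
    and a positive ambient rate.
    """

    genus: str
    infected_fraction: float = 0.0
    mean_umis: float = 6.0
    dispersion: float = 1.5
    ambient_read_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.infected_fraction <= 1.0:
            raise ValueError("infected_fraction must be in [0, 1]")
        if self.mean_umis < 0 or self.ambient_read_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one synthetic experiment.

    The defaults describe a 500-cell co-culture-style run with one focal
    genus infecting 25% of cells, moderate PCR duplication, and both
    libraries observing each molecule with high probability.
    """

    seed: int
    n_cells: int = 500
    sample: str = "sim"
    barcode_length: int = 16
    umi_length: int = 10
    taxa: tuple[TaxonConfig, ...] = (
        TaxonConfig(genus="Fusobacterium", infected_fraction=0.25),
    )
    duplication_rate: float = 0.5  # expected extra reads per UMI per library
    p_gex: float = 0.7  # per-UMI capture probability in the GEX library
    p_amplicon: float = 0.9  # per-UMI capture probability in the amplicon library
    misassignment_rate: float = 0.0
    host_reads_per_cell: float = 2.0
    read_length: int = 120
    base_quality: int = 37
    n_genes: int = 200
    n_signal_genes: int = 0
    signal_log2fc: float = 1.0
    base_expression_mean: float = 2.0
    signal_expression_mean: float = 5.0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if not self.taxa:
            raise ValueError("at least one taxon required")
        if not (0 < self.p_gex <= 1 and 0 < self.p_amplicon <= 1):
            raise ValueError("capture probabilities must be in (0, 1]")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")


@dataclass
class SimulatedDataset:
    """Paths to the generated inputs plus in-memory truth tables."""

    outdir: Path
    whitelist: Path
    gex_alignments: Path
    amplicon_alignments: Path
    gex_hits: Path
    amplicon_hits: Path
    scores_csv: Path
    expression_dir: Path
    truth_reads: pd.DataFrame  # read_name, cell_id, genus, umi, library
    truth_counts: pd.DataFrame  # cell_id, genus, true_umis
    truth_cells: pd.DataFrame  # cell_id + per-genus infected flags
    truth_genes: pd.DataFrame  # gene, log2fc
    barcodes: list[str]


def _rng(seed: int, purpose: str, taxon: str | None = None) -> np.random.Generator:
    """A dedicated generator per (seed, purpose, taxon) so that changing one
    parameter never shifts unrelated draws."""
    entropy = [int(seed), _PURPOSES[purpose]]
    if taxon is not None:
        entropy.append(sum(ord(c) * 31**i for i, c in enumerate(taxon)) % (2**31))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _unique_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seqs: dict[str, None] = {}
    while len(seqs) < n:
        seqs.setdefault(_random_seq(rng, length))
    return list(seqs)


def build_toy_taxonomy(genera: Sequence[str], species_per_genus: int = 2):
    """A small taxonomy table (as scores-CSV rows) with two species ids per
    genus plus the genus-level id itself; returns (DataFrame, genus -> ids)."""
    rows = []
    genus_ids: dict[str, list[int]] = {}
    next_id = itertools.count(1000)
    for genus in genera:
        base = [
            ("kingdom", "Bacteria"),
            ("phylum", f"{genus}_phylum"),
            ("family", f"{genus}aceae"),
            ("genus", genus),
        ]
        gid = next(next_id)
        rows.append(
            {
                "tax_id": gid,
                "taxonomy": format_lineage(base),
                "type": "genus",
                "name": genus,
            }
        )
        ids = []
        for s in range(species_per_genus):
            sid = next(next_id)
            lineage = base + [("species", f"{genus}_sp{s + 1}")]
            rows.append(
                {
                    "tax_id": sid,
                    "taxonomy": format_lineage(lineage),
                    "type": "species",
                    "name": f"{genus}_sp{s + 1}",
                }
            )
            ids.append(sid)
        genus_ids[genus] = ids
    return pd.DataFrame(rows), genus_ids


def _sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": "chr1", "LN": 10_000_000}],
        }
    )


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    seq: str,
    qual: int,
    mapped: bool,
    rng: np.random.Generator,
    cb: str | None = None,
    ub: str | None = None,
) -> pysam.AlignedSegment:
    aln = pysam.AlignedSegment(header)
    aln.query_name = name
    aln.query_sequence = seq
    aln.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    if mapped:
        aln.reference_id = 0
        aln.reference_start = int(rng.integers(0, 1_000_000))
        aln.cigarstring = f"{len(seq)}M"
        aln.mapping_quality = 255
        aln.flag = 0
    else:
        aln.flag = 4
        aln.reference_id = -1
        aln.reference_start = -1
    tags = []
    if cb is not None:
        tags.append(("CB", cb))
    if ub is not None:
        tags.append(("UB", ub))
    aln.set_tags(tags)
    return aln


def infected_cells(
    config: SimulationConfig, taxon: TaxonConfig, n_override: float | None = None
) -> np.ndarray:
    """Indices of cells truly infected by ``taxon`` (rank-coupled in the
    infected fraction)."""
    u = _rng(config.seed, "infection", taxon.genus).random(config.n_cells)
    fraction = taxon.infected_fraction if n_override is None else n_override
    k = int(round(fraction * config.n_cells))
    if k == 0:
        return np.array([], dtype=int)
    return np.sort(np.argsort(u, kind="stable")[:k])


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> SimulatedDataset:
    """Generate all pipeline inputs plus ground-truth tables.

    Writes: gzipped barcode whitelist; GEX and amplicon SAM files with CB/UB
    tags; taxonomy-annotated SAMs with per-read YP hits; the classifier
    scores CSV carrying the lineage table; a CellRanger-layout expression
    matrix; truth tables as TSV.  Identical config + seed give identical
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample = config.sample

    bc_rng = _rng(config.seed, "barcodes")
    raw_barcodes = _unique_seqs(bc_rng, config.n_cells, config.barcode_length)
    barcodes = [bc + "-1" for bc in raw_barcodes]
    whitelist_path = outdir / "barcodes.tsv.gz"
    write_barcode_whitelist(set(barcodes), whitelist_path)

    genera = [t.genus for t in config.taxa]
    scores, genus_ids = build_toy_taxonomy(genera)
    other_pool = {
        g: [i for gg, ids in genus_ids.items() if gg != g for i in ids]
        for g in genera
    }
    scores_csv = outdir / f"{sample}.scores.csv"
    scores.to_csv(scores_csv, index=False)

    truth_rows: list[dict] = []
    gex_reads: list[tuple[str, str, str | None, str | None, bool]] = []
    amp_reads: list[tuple[str, str, str | None, str | None, bool]] = []
    hits: dict[str, list[int]] = {}
    read_counter = itertools.count()

    for taxon in config.taxa:
        cells = infected_cells(config, taxon)
        umi_rng = _rng(config.seed, "umis", taxon.genus)
        read_rng = _rng(config.seed, "reads", taxon.genus)
        # NB(mean, size): numpy parameterization n=size, p=size/(size+mean)
        size = taxon.dispersion
        p_nb = size / (size + taxon.mean_umis) if taxon.mean_umis > 0 else 1.0
        loads = umi_rng.negative_binomial(size, p_nb, size=cells.size)
        for cell_idx, n_umis in zip(cells, loads):
            if n_umis == 0:
                continue
            barcode = barcodes[cell_idx]
            umis = _unique_seqs(umi_rng, int(n_umis), config.umi_length)
            for umi in umis:
                in_gex = read_rng.random() < config.p_gex
                in_amp = read_rng.random() < config.p_amplicon
                if not (in_gex or in_amp):
                    in_amp = True  # condition on >=1 library observing it
                for library, present in (("gex", in_gex), ("amplicon", in_amp)):
                    if not present:
                        continue
                    n_reads = 1 + read_rng.poisson(config.duplication_rate)
                    for _ in range(n_reads):
                        name = f"read{next(read_counter):07d}"
                        ids = _hit_ids(
                            read_rng,
                            genus_ids[taxon.genus],
                            other_pool[taxon.genus],
                            config.misassignment_rate,
                        )
                        hits[name] = ids
                        rec = (name, _random_seq(read_rng, config.read_length),
                               barcode, umi, False)
                        (gex_reads if library == "gex" else amp_reads).append(rec)
                        truth_rows.append(
                            {
                                "read_name": name,
                                "cell_id": f"{sample}_{barcode}",
                                "genus": taxon.genus,
                                "umi": umi,
                                "library": library,
                            }
                        )

        amb_rng = _rng(config.seed, "ambient", taxon.genus)
        n_ambient = amb_rng.poisson(taxon.ambient_read_rate)
        for _ in range(n_ambient):
            name = f"read{next(read_counter):07d}"
            hits[name] = _hit_ids(amb_rng, genus_ids[taxon.genus], [], 0.0)
            if amb_rng.random() < 0.5:
                cb: str | None = None  # droplet-free ambient molecule
            else:
                cb = _random_seq(amb_rng, config.barcode_length) + "-1"
                if cb in set(barcodes):  # vanishingly rare; keep it invalid
                    cb = cb[:-2] + "-9"
            ub = _random_seq(amb_rng, config.umi_length)
            rec = (name, _random_seq(amb_rng, config.read_length), cb, ub, False)
            (gex_reads if amb_rng.random() < 0.5 else amp_reads).append(rec)

    host_rng = _rng(config.seed, "host")
    n_host = host_rng.poisson(config.host_reads_per_cell * config.n_cells)
    for _ in range(n_host):
        name = f"read{next(read_counter):07d}"
        barcode = barcodes[int(host_rng.integers(0, config.n_cells))]
        rec = (name, _random_seq(host_rng, config.read_length), barcode,
               _random_seq(host_rng, config.umi_length), True)
        gex_reads.append(rec)

    header = _sam_header()
    paths = {}
    for label, reads in (("gex", gex_reads), ("amplicon", amp_reads)):
        order_rng = _rng(config.seed, "reads", f"__order_{label}")
        order = order_rng.permutation(len(reads))
        aln_path = outdir / f"{sample}.{label}.sam"
        with pysam.AlignmentFile(str(aln_path), "w", header=header) as fh:
            for i in order:
                name, seq, cb, ub, mapped = reads[i]
                fh.write(
                    _make_read(header, name, seq, config.base_quality, mapped,
                               order_rng, cb, ub)
                )
        hits_path = outdir / f"{sample}.{label}.hits.sam"
        with pysam.AlignmentFile(str(hits_path), "w", header=header) as fh:
            for i in order:
                name, seq, cb, ub, mapped = reads[i]
                if name not in hits:
                    continue
                aln = _make_read(header, name, seq, config.base_quality, False,
                                 order_rng)
                aln.set_tag("YP", ",".join(str(t) for t in hits[name]))
                fh.write(aln)
        paths[label] = (aln_path, hits_path)

    truth_reads = pd.DataFrame(
        truth_rows, columns=["read_name", "cell_id", "genus", "umi", "library"]
    )
    if truth_reads.empty:
        truth_counts = pd.DataFrame(columns=["cell_id", "genus", "true_umis"])
    else:
        truth_counts = (
            truth_reads.groupby(["cell_id", "genus"])["umi"]
            .nunique()
            .reset_index(name="true_umis")
        )
    truth_cells = pd.DataFrame({"cell_id": [f"{sample}_{bc}" for bc in barcodes]})
    for taxon in config.taxa:
        flags = np.zeros(config.n_cells, dtype=bool)
        flags[infected_cells(config, taxon)] = True
        truth_cells[taxon.genus] = flags

    expr_dir, truth_genes = _simulate_expression(config, barcodes, outdir)

    truth_reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    truth_counts.to_csv(outdir / "truth_counts.tsv", sep="\t", index=False)
    truth_cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)

    return SimulatedDataset(
        outdir=outdir,
        whitelist=whitelist_path,
        gex_alignments=paths["gex"][0],
        amplicon_alignments=paths["amplicon"][0],
        gex_hits=paths["gex"][1],
        amplicon_hits=paths["amplicon"][1],
        scores_csv=scores_csv,
        expression_dir=expr_dir,
        truth_reads=truth_reads,
        truth_counts=truth_counts,
        truth_cells=truth_cells,
        truth_genes=truth_genes,
        barcodes=barcodes,
    )


def _hit_ids(
    rng: np.random.Generator,
    own_ids: list[int],
    other_ids: list[int],
    misassignment_rate: float,
) -> list[int]:
    ids = [own_ids[int(rng.integers(0, len(own_ids)))]]
    if other_ids and rng.random() < misassignment_rate:
        ids.append(other_ids[int(rng.integers(0, len(other_ids)))])
    return ids


def _simulate_expression(
    config: SimulationConfig, barcodes: list[str], outdir: Path
) -> tuple[Path, pd.DataFrame]:
    """Poisson count matrix with configured fold changes on signal genes
    between cells truly infected by the first infectable taxon and the rest;
    written in CellRanger filtered-matrix layout."""
    rng = _rng(config.seed, "expression")
    focal = next((t for t in config.taxa if t.infected_fraction > 0), None)
    positive = np.zeros(config.n_cells, dtype=bool)
    if focal is not None:
        positive[infected_cells(config, focal)] = True

    genes = [f"GENE{j:04d}" for j in range(config.n_genes)]
    signal = np.zeros(config.n_genes, dtype=bool)
    signal[: config.n_signal_genes] = True
    mean = np.where(
        signal, config.signal_expression_mean, config.base_expression_mean
    ).astype(float)
    lam = np.tile(mean, (config.n_cells, 1))
    lam[np.ix_(positive, signal)] *= 2.0 ** config.signal_log2fc
    counts = rng.poisson(lam)

    expr_dir = outdir / "filtered_feature_bc_matrix"
    expr_dir.mkdir(exist_ok=True)
    # CellRanger layout stores genes x cells
    mmwrite(str(expr_dir / "matrix.mtx"), csr_matrix(counts.T))
    with open(expr_dir / "features.tsv", "wt") as fh:
        for g in genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(expr_dir / "barcodes.tsv", "wt") as fh:
        for bc in barcodes:
            fh.write(bc + "\n")
    truth_genes = pd.DataFrame(
        {"gene": genes, "log2fc": np.where(signal, config.signal_log2fc, 0.0)}
    )
    return expr_dir, truth_genes


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Agreement between generator truth and pipeline output."""

    exact_match_fraction: float
    sensitivity: float
    specificity: float
    n_true_positive_cells: int
    n_detected_positive_cells: int
    mean_signal_log2fc: float | None = None
    log2fc_correlation: float | None = None


def evaluate_recovery(
    truth_counts: pd.DataFrame,
    truth_cells: pd.DataFrame,
    matrix: GenusCellMatrix,
    taxon: str,
    pos_threshold: int = 1,
    de_results: pd.DataFrame | None = None,
    truth_genes: pd.DataFrame | None = None,
) -> RecoveryReport:
    """Compare pipeline counts and positive-cell calls against ground truth.

    exact_match_fraction is over all (cell, genus) pairs nonzero in either
    table; sensitivity/specificity are for positive-cell detection of
    ``taxon`` at ``pos_threshold`` over the whole cell universe.
    """
    truth_map = {
        (r.cell_id, r.genus): int(r.true_umis)
        for r in truth_counts.itertuples(index=False)
    }
    universe = set(truth_cells["cell_id"])
    pipe_map = {
        (c, g): len(umis) for c, g, umis in matrix.iter_entries() if umis
    }
    if not set(c for c, _ in pipe_map) <= universe:
        raise ValueError("pipeline matrix contains cells outside the truth universe")
    keys = set(truth_map) | set(pipe_map)
    exact = (
        sum(truth_map.get(k, 0) == pipe_map.get(k, 0) for k in keys) / len(keys)
        if keys
        else 1.0
    )

    truly_pos = {
        r.cell_id for r in truth_cells.itertuples(index=False)
        if taxon in truth_cells.columns and getattr(r, taxon)
    }
    detected = {
        c for (c, g), n in pipe_map.items() if g == taxon and n >= pos_threshold
    }
    tp = len(truly_pos & detected)
    fp = len(detected - truly_pos)
    fn = len(truly_pos - detected)
    tn = len(universe) - tp - fp - fn
    sensitivity = tp / (tp + fn) if (tp + fn) else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0

    mean_lfc = corr = None
    if de_results is not None and truth_genes is not None:
        signal = truth_genes.loc[truth_genes["log2fc"] != 0, "gene"]
        est = de_results["log2_fold_change"].reindex(signal).dropna()
        if len(est):
            mean_lfc = float(est.mean())
        common = de_results.index.intersection(truth_genes["gene"])
        true_vec = truth_genes.set_index("gene")["log2fc"].reindex(common)
        est_vec = de_results["log2_fold_change"].reindex(common)
        if true_vec.std() > 0 and est_vec.std() > 0:
            corr = float(np.corrcoef(true_vec, est_vec)[0, 1])
    return RecoveryReport(
        exact_match_fraction=exact,
        sensitivity=sensitivity,
        specificity=specificity,
        n_true_positive_cells=len(truly_pos),
        n_detected_positive_cells=len(detected),
        mean_signal_log2fc=mean_lfc,
        log2fc_correlation=corr,
    )
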