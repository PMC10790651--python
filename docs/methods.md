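# Methods

## Quantification model

Each droplet partition (GEM) tags every captured molecule with a cell
barcode (CB) and a UMI. A bacterial transcript captured in a cell's droplet
can be sequenced several times (PCR duplication) and by two libraries — the
5′ gene-expression (GEX) library and the 16S-enrichment library built from
the same amplified cDNA — but it remains one molecule. The pipeline's unit
of measurement is therefore the distinct (cell barcode, genus, UMI sequence)
triplet, and the central container (`GenusCellMatrix`) stores UMI *sets*
per (cell, genus) so deduplication is structural: counts are always derived
as set cardinalities, and inserting the same observation twice is a no-op.

Candidate reads must be primary alignments carrying a whitelisted barcode
and a UMI. In the GEX library, bacterial transcripts appear among
host-unmapped reads, so host-mapped reads are excluded there; the amplicon
library is 16S-targeted, so host-mapping status is ignored. Barcodes are
compared verbatim against the GEX whitelist (including the GEM-well suffix,
e.g. `-1`); the amplicon library is filtered against the *GEX* whitelist so
that only droplets confirmed as cells contribute. Raw uncorrected tags
(CR/UR) are never read. UMIs are compared by exact sequence; no 1-mismatch
network collapsing is attempted, which is conservative (sequencing errors in
UMIs inflate counts slightly) but exactly reproducible.

## Genus assignment

Taxonomic resolution is deliberately capped at genus. A read's classifier
hits (all best-scoring taxon ids) are collapsed with a conservative rule:
the read is assigned if and only if every hit's lineage contains the same
single genus; species- and strain-level ids collapse upward, ids whose
lineage carries no genus rank (family and above) contribute `None`, and any
disagreement leaves the read `unassigned`. Unassigned reads appear in the
read-level audit table but never in the matrix — fractional or
above-genus counting would break the integer molecule-count semantics.
Probable reagent contaminants (*Patulibacter*, *Pseudomonas*,
*Sphingomonas*) ship as an optional, documented denylist preset; the
default denylist is empty. Denylisting removes genus columns but retains
cells (their totals become 0), is idempotent, and commutes with merging.

## Read-1 trimming (amplicon path)

Operators apply per read in the order: adapter clip, HEADCROP (default 15),
LEADING (Q < 3), TRAILING (Q < 3), SLIDINGWINDOW (4 bases, mean Q < 15: cut
at the window start, then strip trailing bases below the window threshold),
MINLEN (36). HEADCROP precedes the quality steps and MINLEN is evaluated
last, on the final length. Adapter clipping is simplified relative to
seed-and-extend trimmers: the read is truncated at the leftmost exact
occurrence of any adapter, or at a 3′-terminal match to an adapter prefix of
at least 10 bases. This simplification is a deliberate design choice and is
tested against an independently written straight-line reference of the same
definitions, not against external trimmers. Trimming gates which reads reach
the classifier in end-to-end runs; the quantifier itself accepts
post-classification hits.

## Merging

Merging unions the per-(cell, genus) UMI sets of any number of matrices and
re-derives counts, recording per-triplet source provenance. The operation is
commutative, associative and idempotent, and merged counts are bounded above
by the sum of inputs with equality iff no triplet overlaps. Because counts
alone cannot be deduplicated, merging requires the UMI-set sidecar files;
bare count CSVs are refused. Cell ids are `sample_barcode`, so cross-sample
merging never deduplicates across samples.

## Bacteria-status analysis

Cell grouping uses a threshold predicate: Positive when the focal genus (or
the per-cell total) has ≥ *t* UMIs (*t* = 4 by default, exposed as a
parameter; ≥ rather than > follows the executable grouping predicate),
Negative when the cell has zero bacterial UMIs, otherwise excluded (NA) —
cells with 1..*t*−1 UMIs are too ambiguous to call. Raising *t* can only
shrink the Positive set.

Expression is log-normalized (per-cell scaling to 10,000 counts, then
log1p). Genes detected in ≥ `min_pct` (default 0.1) of either group are
tested with a two-sided Wilcoxon rank-sum (Mann–Whitney) test — exact when
group sizes permit and the data are tie-free, normal approximation with tie
correction otherwise; genes constant across both groups are assigned p = 1.
Fold change is log2((mean expm1 normalized expression in Positive + 1) /
(mean in Negative + 1)); the +1 pseudocount stabilizes low expressors and
shrinks estimates slightly toward zero. BH adjustment runs over tested genes
only. Volcano reporting flags |log2FC| ≥ 0.58 and −log10 p ≥ 1.301; these
are reporting thresholds, not test parameters.

Preranked GSEA ranks genes by descending fold change (ties broken by gene
name for determinism) and walks a weighted Kolmogorov–Smirnov running sum
with weight exponent 1 on |value|: hits step up proportionally to their
weight, misses step down by 1/(N − N_hit). ES is the signed maximum
deviation (first occurrence on ties). Degenerate cases are defined
explicitly: when every ranked gene is a hit there are no miss steps and the
running sum climbs to ES = 1; when all hit weights are zero, equal
increments are used. The null shuffles hit labels (default 1,000
permutations, explicit seed); NES divides ES by the mean |null ES| of
matching sign (the sign-matched normalization is a declared choice), and the
two-sided p-value is (1 + #{|ES_null| ≥ |ES|}) / (n_perm + 1). A set
disjoint from the ranking is reported untestable rather than failing the
run.

## Synthetic data

The generator emulates the validation designs the method rests on, with
full read-level ground truth:

- **Dose response** — per-taxon infected fractions stand in for
  multiplicity of infection; infected cells draw negative-binomial distinct
  UMI loads (default mean 6, dispersion 1.5 — heavy-tailed, matching the
  observation that a few cells carry >100 bacterial transcripts while many
  carry one or none). Infected-cell selection is rank-coupled: each cell
  draws one dedicated uniform per taxon and the round(fraction·n) smallest
  are infected, so a larger fraction under the same seed infects a superset
  of cells and group sizes are exact.
- **Two-library observation** — each true UMI is seen by the GEX library
  with probability 0.7 and the amplicon library with 0.9 (conditioned on at
  least one), each observation duplicated 1 + Poisson(0.5) times, creating
  the overlap that merging must deduplicate.
- **Nonadherent control** — a taxon with infected fraction 0 and a positive
  ambient read rate emits reads with no valid barcode (or a random
  non-whitelisted one); they reach the classifier but must contribute zero
  cell-associated UMIs.
- **Host expression** — Poisson counts (base mean 2 per gene) with
  configured log2 fold changes on signal genes (mean 5) between truly
  infected and uninfected cells, written in CellRanger MTX layout.
- **Classifier emulation** writes per-read taxon hits directly; a
  misassignment probability (default 0) adds a second-genus hit to exercise
  the unassigned path.

The generator does **not** simulate sequence-level realism: no base-calling
error profiles, chimeras, barcode errors, index hopping, or genuine 16S
sequence content. Passing tests therefore demonstrate the correctness of
the counting, merging and testing machinery under the stated generative
model — not robustness to classifier error or barcode corruption in real
data.

## Numerical and design notes

- Problem sizes in the test suite and acceptance script (up to ~600 cells,
  500 genes, 10–20 simulated datasets) were chosen as the smallest scales at
  which the statistical properties under test are stable.
- The recovered mean log2FC for implanted signal genes sits slightly below
  the configured value (≈0.85 for a configured 1.0): signal genes raise
  positive cells' library sizes, deflating their normalized values, and the
  +1 pseudocount shrinks ratios — both are properties of the estimator, not
  errors.
- The Wilcoxon null calibration uses generator-truth group labels so group
  sizes are exact; the type-I error rate lands in the nominal band.
- All randomness flows through explicit seeds; per-purpose child generators
  mean changing one simulation parameter never shifts unrelated draws, and
  identical config + seed yields byte-identical artifacts.
- Stage orchestration is file-based with parameter-hash done-markers:
  rerunning a completed stage with identical parameters is a no-op unless
  forced.

## Limitations

- No barcode or UMI error correction; counts are conservative.
- The concordant-genus rule discards genuinely informative multi-hit reads
  whose hits span genera (no fractional assignment).
- Adapter clipping is exact-match/prefix-overlap only.
- Clustering, embedding, dataset integration and cell-type annotation are
  out of scope; cell-type labels, if available, are consumed as metadata.
- The merged matrix treats identical (cell, genus, UMI) triplets across
  libraries as one molecule; distinct molecules that happen to share a UMI
  within a cell and genus (UMI collision) are undercounted, as in any
  distinct-UMI scheme.
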