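# Methods

## The screen

The pipeline takes a probe × sample intensity matrix with an explicit scale
tag (`log2` or `linear`; never inferred from value ranges, since silent
misdetection would corrupt fold-changes by orders of magnitude), a cohort
design assigning each sample to exactly one group, and a probe annotation
(gene symbol, plasma-membrane flag, gene-family tag, symbol-alias table).
For each comparator panel it computes, per probe:

* **fold-change** — the ratio of *linear*-scale group means. Arrays are
  un-logged before averaging; the comparator mean is floored at ε
  (default 1.0 linear intensity unit) so near-zero denominators cannot
  inflate the ratio without bound. With both means above ε, swapping the
  groups yields the reciprocal.
* **T score** — the two-sample t statistic on log2 intensities. Welch's
  form is the default because comparator panels (a broad multi-tissue
  collection vs. a homogeneous PBMC panel) have unequal variances by
  construction; a pooled-variance variant is available and recorded in
  output metadata. Degenerate probes: zero variance in both groups with
  equal means gives t = 0; zero variance with unequal means gives a signed
  infinity rather than an error.
* **gene-vs-outcome Pearson r** — the point-biserial correlation between a
  probe's log2 values and 0/1 disease membership over the disease +
  comparator samples. Disease is coded 1, so positive r means disease-high
  and comparator-class markers come out negative. Constant probes get an
  undefined flag (NaN) rather than 0, so they can be excluded explicitly.

Scores are then restricted to membrane-flagged probes and the top N are
taken per metric, descending, with ties broken by canonical symbol then
probe id so a re-run is byte-identical. The default pipeline is
probe-level — distinct probes of one gene rank separately, as array screens
report them — and probe→gene collapsing (`max_mean` or `mean`) is an
opt-in reporting convenience.

## List comparison

Cross-list matching is at the gene level on canonical symbols (published
lists do not always print probe ids). Canonicalization is one application
of a curated alias map (e.g. CD62L→SELL, MHMA1→HMHA1, TCRDC→TRDC); the map
is idempotent, unknown symbols map to themselves, and immunoglobulin loci
are deliberately *not* merged (IGH ≠ IGHM, which screens list as distinct
hits). Distinct TCR variable/constant-chain entries are likewise distinct
transcripts.

`shared_fraction` reports the strict intersection of two lists' canonical
symbol sets; the percentage is relative to the query list's size by default
(the newer comparison's top-N checked against a reference list), with
`len_b` and `union` rules available. `consensus` pools each comparator's
lists across metrics (a gene counts once per comparator) and counts, per
gene, the comparators containing it — genes at K-of-K are the
highest-priority targets. The bundled reference lists reproduce the
published cross-comparator statistics exactly (60% HSC/T-score overlap, 15%
PBMC/fold-change overlap, HHIP 3-of-3, TSPAN7 2-of-3, 11 of 46 clonotypic
hits); note the strict T-/B-list intersection is 16 symbols, one more than
the source's enumerated 15, because ICAM-3 appears in both printed columns —
the package reports the strict count rather than reproducing the tally.

## Z-scoring and clustering

Z-scoring is per probe row, `(x − mean)/SD` with the **sample** (n−1) SD —
the common expression-analysis convention; the population/sample choice is
fixed and documented because it changes every z-value by √(n/(n−1)). The
statistics can be computed over a named subset (e.g. leukemia samples only)
and applied to all columns. Constant rows become all-zero and are flagged
rather than erroring, so uninformative probes do not break clustering.

Sample clustering is agglomerative on z-scored rows. The shipped pipeline
first selects the most-variable genes (default 100) on the *raw* log2
matrix — selection after z-scoring would be vacuous, as every standardized
row has unit variance — mirroring how expression heatmaps are built on a
selected gene axis. The default distance is **1 − Pearson correlation**
with **average linkage**: correlation distance compares profile shape
rather than magnitude, which in simulation proved markedly more robust than
Euclidean distance, where a single high-variance sample is peeled off as a
singleton at k = 2 (collapsing two-class accuracy to ~0.5 on a noticeable
fraction of random cohorts). Euclidean distance and complete/single
linkages remain available. Partitions are obtained by cutting the k−1
highest merges; agreement with known classes is best-match accuracy
(optimal one-to-one cluster↔label assignment, solved exactly via the
assignment problem and cross-checked against exhaustive enumeration for
small k). Adjusted indices were considered and not made the primary metric
because the claim being checked is plain partition correspondence.

## Synthetic cohorts

`generate_cohort` draws log2 intensities as

    x_gs = baseline_g + δ · 1[gene g planted for sample s's group] + N(0, σ)

with per-gene baselines from Normal(6, 1.5) truncated below at 2 (log2
units typical of processed arrays) and σ = 1 by default. Three comparator
panels emulate the screening design: `broad` (no planted elevation),
`stemlike` (its own planted stem set, n = 14 — the HSC panel size), and
`maturelike` (expresses the **lineage** set at the same δ as the disease,
the cleanest encoding of a shared lineage program; n = 15, the PBMC panel
size). The disease cohort (n = 15) elevates lineage + tumor sets. Default
gene counts are 30 lineage, 5 tumor, 10 stem among 2000 probes; planted
genes are always membrane-flagged, other genes are membrane with
probability 0.3. One seeded NumPy generator drives everything, so a cohort
is a pure function of its spec and byte-identical across runs.

What the generator does *not* model: probe-level cross-hybridization,
batch/array effects, correlated co-expression modules, missing values, and
heavy-tailed noise. Passing recovery tests therefore show the pipeline's
logic is correct under idealized log-normal noise, not that real cohorts of
this size would give the same power.

`recovery_report` summarizes a screen against the planted truth: fraction
of tumor genes in the broad-panel top list, fraction of lineage genes that
appear against the broad panel but drop out against the maturelike panel,
and fraction of tumor genes at full consensus.

## Study sizes used in tests and the acceptance script

Null calibration uses one no-effect cohort of 2000 probes, 15 vs 15; the
fraction of |t| beyond the per-probe Welch 5% critical value is checked
against 0.05 ± 0.02 and the mean fold-change against (0.8, 1.25). Recovery
uses 20 cohorts at δ = 4 (strong signal); the comparator contrast uses 20
cohorts at δ = 3 with 30 lineage + 5 tumor genes and top-35 lists, asking
that the broad↔stemlike overlap exceed the broad↔maturelike overlap in at
least 18 of 20 — the qualitative form of the published 60–70% vs 10–15%
contrast. Clustering uses 20 two-class cohorts at the hardest stipulated
regime (20 markers, δ = 2, σ = 1) and requires mean k=2 accuracy ≥ 0.95.
These sizes keep the full suite to a few minutes on one CPU while leaving
clear statistical margin on every check.

## Numerical and degenerate-input conventions

* Missing cells are an error, not imputed — the statistics assume complete
  matrices.
* `to_log2` of a linear matrix containing 0 requires a positive
  pseudocount; the default pseudocount is 0 so the failure is explicit.
* Ranking is stable (mergesort) with a total tie-break order, and every
  writer emits fixed column orders, so outputs are reproducible to the byte.
* Matrix round-trips preserve up to 12 significant digits (`%.12g`).
* Correlation values are clipped to [−1, 1] against floating-point drift.

## Known limitations

* The screen ranks by raw scores; no p-values or multiple-testing
  correction (the method ranks, it does not test), and no moderated
  variance estimators.
* Overlap statistics carry no significance model (no hypergeometric or
  permutation p-values).
* The alias table is curated and version-pinned with the fixtures; there
  are no live symbol-service lookups, by design.
* CEL-file processing and array normalization are out of scope — the
  pipeline consumes preprocessed matrices.
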