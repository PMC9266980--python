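# Methods

This note documents the models and numerical choices behind `mirsig`, what
the synthetic data emulate, and the limits of what the test suite can show
about real data.

## Input model

The universal carrier is a non-negative miRNA × column matrix
(`ExpressionMatrix`), where a column is a single cell, an aggregated cell
type, or a bulk sample.  Values are assumed to be on an additive scale
(CPM or summed peak scores); duplicated miRNA rows are therefore combined
by summation by default (`combine="mean"` is available for intensity-like
units).  miRNA identifiers are lowercased and matched only on exact
strings — no fuzzy matching, to avoid silent mis-merges between precursor
and mature-arm names.  Whether rows are precursor- or arm-resolution is
the caller's choice; the pipeline is agnostic.

Genomic coordinates are 1-based inclusive throughout (the GFF3
convention); BED input is converted at the parser boundary.  The GFF3
reader keeps `miRNA_primary_transcript` features by default because
gene-level coordinates are the natural anchor for a chromatin window;
mature `miRNA` features can be selected instead.

## Chromatin activity

Activity of miRNA *g* in cell *c* is the sum of scores of all peaks in *c*
whose interval overlaps `[start(g) − w, end(g) + w]` by at least 1 bp,
with `w = 2000` bp by default.  Design choices:

* the window is a flank on **each** side (total span = gene length + 2w);
  `window_bp` makes the alternative reading (half on each side) available;
* any overlap counts in full — no length-proportional weighting, and a
  peak inside two miRNAs' windows contributes its whole score to both,
  since each window's sum is defined independently;
* strand is ignored (accessibility is unstranded);
* peak scores are used as given — no binarization or depth normalization.

Cell-type activity is the arithmetic mean over cells sharing a label.
Overlap is resolved with an interval tree (O((P+M) log M)); the unit tests
check it against a quadratic brute-force loop.

## Joint embedding and signature ranking

Continuous profiles are fuzzy-coded: each miRNA row is min–max scaled
across cell types to `u` and doubled into the complementary pair
`(u, 1−u)`, giving a non-negative cell-type × 2m table whose feature pairs
each sum to one.  Min–max scaling absorbs any per-miRNA affine transform
`a·x + b` (a > 0), so the embedding and every downstream ranking are
invariant to such rescalings (asserted exactly in the tests).  Rows
constant across all cell types have no defined scaling and are dropped
with a warning.

Correspondence analysis of that table: with `P` the table over its grand
total, row masses `r`, column masses `c`, the SVD of the standardized
residuals `S = Dr^{-1/2}(P − rcᵀ)Dc^{-1/2}` gives axes with inertia
`σ_k²`.  The default joint map is **asymmetric**: cell types in standard
coordinates (`Dr^{-1/2}U`), features in principal coordinates
(`Dc^{-1/2}VΣ`).  This was a genuinely open design choice; it is the
convention used here because under it each feature point is exactly the
profile-weighted barycenter of the cell-type points, so an indicator-like
feature lands on its cell type and the cell-to-feature Euclidean distance
is a direct association measure.  The symmetric alternative (both sides
in principal coordinates) down-weights the cell-type points by the
per-axis singular values and, on the planted-signature benchmark below,
recovers fewer than half of the planted miRNAs; it remains available via
`scaling="principal"` (and `"standard"`), since the convention governs
only the relative geometry, not the axes themselves.

The number of retained dimensions defaults to `min(50, n_cell_types − 1)`,
mirroring common practice for MCA-based signature extraction; requests
beyond the numerical rank are truncated with a warning.  Only the positive
member of each doubled pair is ranked — the negative member encodes
absence, and "closest to the cell type" must mean high signal.  Rankings
sort ascending by distance with lexicographic-by-name tie-breaking, which
makes the top-k cut deterministic.

## Gini specificity index

For non-negative `x` over `n ≥ 2` cell types, sorted ascending,

    G = (n+1)/n − 2·Σᵢ (n+1−i)·x₍ᵢ₎ / (n·Σx)
      = Σᵢⱼ |xᵢ − xⱼ| / (2·n·Σx),

bounded in `[0, 1 − 1/n]`.  Note the ordering: applying the weight
`(n+1−i)` to descending-ordered values — a formulation sometimes seen —
flips the sign of the deviation term and yields `−0.5` for the point mass
`(1, 0)`, contradicting the index's meaning; the ascending form used here
is the standard Gini and gives `(1, 0) → 0.5`.  All-zero rows get `G =
NaN` (the specificity of an unobserved miRNA is undefined, not 0 or 1) and
are ineligible for catalogs and correlations.  The Gini is computed on the
same raw matrix that fed the embedding, not on the fuzzy-coded values.

The catalog keeps, per cell type, the top-k (default 20) ranked miRNAs
with `G >` 0.5; both parameters are recorded in the catalog and in the GMT
description field.  A cell type may legitimately end up with an empty
signature.

## Set analysis and enrichment

* Jaccard `J(A,B) = |A∩B|/|A∪B|`, with `J(∅,∅) := 0` — an empty signature
  carries no similarity evidence and must not cluster with other empties.
  Heatmap orders come from average-linkage clustering of `1 − J`.
* Partner counts are distinct-key cardinalities (a TF regulating a miRNA
  through three reported interactions counts once).
* Specificity–covariate association uses Spearman correlation with
  average-rank ties and the large-sample t approximation; an exact
  permutation p-value (full enumeration) is available for n ≤ 10.
* Disease enrichment: upper-tail hypergeometric p per (cell type,
  disease), BH-corrected **per cell type across diseases**, significant at
  q < 0.05.  The universe defaults to the intersection of measured and
  annotated miRNAs — enrichment should not be claimed against miRNAs that
  could never have been observed; an all-annotated option exists.
* Causal association: one-sided (greater) Fisher exact test on the 2×2
  signature-membership × causality table, restricted to diseases with ≥ 5
  causal miRNAs in the universe.  The reported odds ratio is the sample OR
  with a Haldane–Anscombe 0.5 correction when a zero cell occurs; the
  correction never touches the p-value.  Degenerate margins give p = 1.

## Composition scoring (mirCellType)

* **ssGSEA**: per sample, miRNAs are walked in descending expression
  order.  In-set steps advance a weighted CDF with weights
  `rank^alpha` (average ranks, `alpha = 0.25`) normalized to sum 1;
  out-of-set steps advance a uniform CDF.  The score is the sum of the CDF
  differences over all positions (the integrated running-sum variant).
  Ties are deterministic: average ranks feed the weights while the walking
  order breaks ties by input row order.  Degenerate cases: a signature
  covering every measured miRNA has no out-of-set CDF and scores 0; an
  all-zero sample has no ranking and scores NaN.  At `alpha = 0` the score
  depends on ranks alone and is exactly scale-invariant.  Optional
  normalization divides the whole score matrix by its global range (off by
  default).
* **Abundance**: `mean log2(x + pseudocount)` over signature members,
  identically the log2 geometric mean of `(x + pseudocount)`.  The
  pseudocount defaults to 1 on CPM-scale input.

Signature members absent from the expression matrix are dropped with a
count reported, never imputed.  Both scores are relative; the package
deliberately does not do constrained-regression deconvolution, so scores
do not sum to one across cell types.

## Synthetic study conditions

`FixtureSpec` defaults define the benchmark: 30 cell types × 300 miRNAs,
10 planted specific miRNAs per type, fold 20, i.i.d. log-normal background
(`mu = 1`, `sigma = 1` on the log scale, mimicking CPM skew), 50 bulk
mixtures with flat Dirichlet proportions (`alpha = 1`, no preferred
composition) and 20% multiplicative log-normal noise (unit mean).  A
planted miRNA takes the value `fold × E[background]` in its own column — a
controlled, deterministic enrichment over the background level; tying the
boost to the row's own random draw would make the "fold" vary an order of
magnitude across rows and was rejected.  Planted sets are disjoint blocks
by default; `overlap_fraction` shares a prefix of each block with the
neighbouring type to emulate related cell types, and `broad_fraction`
turns leftover rows into broadly expressed decoys (one base level per row
× CV-0.2 jitter, hence low Gini).

What the generator does **not** emulate: real atlas marginals, correlated
cell types, compositional/count noise (sequencing depth), precursor/arm
redundancy, or batch structure.  Passing the planted-recovery and
mixture-recovery benchmarks therefore shows the machinery is correct and
well-conditioned under clean planted structure, not that any particular
recovery rate will hold on real atlases.

The peak-fixture generator lays miRNA genes on a toy chromosome with gaps
wider than twice the window so windows never touch, places peaks
deliberately inside or outside each window, and tallies the expected
activity matrix during placement — the construction itself is the oracle
for the overlap code.

## Numerical choices and degenerate inputs

* SVD via LAPACK with rank detection at `max(dim) · eps · σ₁`; tests
  compare against an independent eigendecomposition route at 1e-8.
* TSV matrices are parsed with round-trip float precision so write→read is
  bitwise exact; MatrixMarket triplets round-trip via scipy.
* Duplicate-row merging is order-independent (grouped sum, first-appearance
  order).
* All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; every generator is bitwise reproducible.

## Problem sizes

Unit tests run on scaled-down conditions (6 × 60) for speed; the
acceptance script and the deeper tests use the full default conditions
(30 × 300, 50 mixtures), chosen to finish comfortably on one CPU while
exercising the benchmark at its defined size.

## Known limitations

* Single-matrix pipeline: expression and chromatin-activity catalogs are
  built in separate runs; no cross-assay harmonization of cell-type names
  (Cell Ontology mapping is manual curation, out of scope).
* No hypothesis test on embedding distances — the cut is rank-based
  (top-k) plus the Gini threshold.
* ssGSEA scores are comparable within a run, not across differently
  normalized datasets.
* The enrichment universe choice materially affects p-values; both
  supported conventions are explicit rather than hidden.
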