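# Methods

This note records the statistical model behind `caracal`, the defaults
that matter, the choices made where several designs were defensible, and
what the synthetic benchmarks do and do not demonstrate.

## Gene-activity projection

Accessibility peaks are attributed to genes by interval overlap. Each
gene's window is its body extended `upstream_bp` (default 2000) bases
upstream of the transcription start: `[start − u, end)` on the + strand,
`[start, end + u)` on the −, clipped at the chromosome origin. All
coordinates are 0-based half-open; GTF input is converted on read, BED and
peak names (`chrom:start-end`, also `chrom-start-end`) are taken as
BED-style. Overlap requires at least one shared base under half-open
arithmetic (`p.start < w.end` and `w.start < p.end`).

Two deliberate semantics, both configurable nowhere (they define the
projection):

* a peak overlapping k gene windows contributes its **full** count to all
  k genes — no splitting, no nearest-gene assignment;
* genes without any overlapping peak are retained as all-zero rows, so
  the output feature space equals the annotation's gene space.

Duplicate gene names in annotations keep the longest record. Activity
matrices produced by other estimators (e.g. co-accessibility models) have
different signal structure; signatures are only valid for the projection
they were built on, and the package makes no attempt to translate between
projections.

## Preprocessing

* Cell filters: minimum/maximum total counts and minimum detected
  features; feature filter: nonzero in at least `min_cells` cells. Filters
  are idempotent and report kept/removed counts.
* Normalization: `v → ln(1 + v · s/T)` with scale factor `s = 10⁴` and `T`
  the cell total; all-zero cells are guarded and map to zeros.
* Variable features: genes with positive mean and variance are ranked by
  binned-dispersion z-score — genes are placed into equal-occupancy bins
  by mean (20 bins, automatically reduced so bins hold roughly 20 or more
  genes; with very few genes a single bin is used), dispersion
  (variance/mean) is z-scored within each bin, ties break by input order.
* Scaling: per-gene center/scale (sample sd, ddof 1) with clipping at ±10;
  zero-variance genes become zero rows.

Scoring operates on the **normalized** layer by default: the distance
statistic is anchored at zero, and centering would erase exactly the
"expression exceeds absence" signal it measures. The scaled layer exists
for visualization-style use and can be selected explicitly.

## Differential activity and signatures

One-vs-rest per cell type on normalized values. Per gene:

* `log2FC = log2((mean(expm1(v_in)) + 1) / (mean(expm1(v_out)) + 1))` —
  means are computed on back-transformed values with a pseudocount of 1,
  which keeps the statistic finite for all-zero groups;
* two-sided Wilcoxon rank-sum p-value. When the smaller group exceeds 8
  cells, the tie-corrected normal approximation with continuity correction
  is used. Otherwise the exact permutation null is enumerated by a
  subset-sum convolution over doubled midranks, which handles ties exactly
  (the float64 counts are exact below 2⁵³);
* Bonferroni adjustment over tested genes. Genes are tested only when
  nonzero in at least `min_pct` (default 0.01) of either group. Adjusted
  p-values are reported for transparency but play no role in selection,
  which is purely by log2FC rank.

The up-set takes the `n_genes` (default 100) largest positive log2FC
genes, the down-set the most negative; weights are |log2FC| so both
directions share one positive scale (a raw fold-change scale is available
via `weight_scale="fc"`). Ties break by smaller p-value, then gene id. A
direction with no qualifying genes yields an empty set, which the scoring
layer treats as absent. The 100-gene default is intentionally larger than
typical scRNA-seq signatures: projected activity is noisier, and set-level
scoring averages that noise down.

## Variance-adjusted scoring and the gamma null

For a set with raw weights rescaled to mean one over the genes present in
the matrix (absent genes are dropped with a warning),

    d²ᵢ = Σₖ w̃ₖ · x²ᵢₖ / max(σ̂²ₖ, ε),      ε = 1e−8,

with σ̂²ₖ the per-gene sample variance across cells (ddof 1). The variance
estimator is a pluggable argument of `compute_vam_distances`, so a
technical-noise model can be substituted without touching the scoring
path. Mean-one weight renormalization makes scores comparable across sets
of different sizes and invariant to rescaling all weights by a constant.

The null permutes each set gene independently across cells (breaking
within-cell coordination, preserving marginals) and resamples rows to
`n_permutations` (default 1000, minimum 100) synthetic null cells. A gamma
distribution is fitted to the null d² — method of moments by default
(`shape = mean²/var`, `rate = mean/var`); an MLE refinement by Newton
iterations on the shape equation is available — and scores are
`GammaCDF(d²)`. `1 − score` is a p-value.

The gamma is an approximation to the true permutation distribution. On
iid noise its CDF agrees with empirical null quantiles to within about
0.03–0.05 sup-norm at typical set sizes (30–100 genes); sets whose genes
have strongly multimodal marginals can sit at the upper end of that range.
When exact tail probabilities matter more than speed, raise
`n_permutations` and compare against empirical quantiles directly.

## Combination, labeling, integration

* Combined score per cell and type: `up + (1 − down)` ∈ [0, 2]. A type
  without a down-set has its down score pinned at 1 (contributing 0) and
  is flagged `up_only` — conservative, since such a type can reach at most
  1 while others reach 2.
* Labels: argmax of the combined score; exact ties resolve to the
  lexicographically smallest type and are flagged; `margin` is the lead
  over the runner-up; tops below `min_score` become `unassigned`.
* Integration: `rna(i,j) · [atac(i,j) > median_j]`, medians per type over
  all cells. The inequality is strict — a score exactly at the median
  gates to zero; with an even number of distinct scores the pandas/numpy
  linear-interpolation median falls between order statistics, so exactly
  half the cells pass. Inputs are aligned by barcode and type name, not
  position. Either [0, 1] or [0, 2] score scales are accepted; the gated
  output inherits the RNA scale.

## The simulator: what it emulates, what it does not

Counts are negative binomial with mean `baseline_mean · effect_fold^s`
(`s = +1` for the type's up-markers, `−1` for down-markers, else 0) and
fixed dispersion `r` (variance `μ + μ²/r`). Marker sets are disjoint
across types and directions. Defaults — 3 types × 200 cells, 2000 genes,
100 up + 100 down markers per type, fold 4, baseline mean 2, dispersion 2
— define the benchmark conditions used throughout the tests, chosen as a
moderately sparse activity matrix (about a quarter of entries zero at
baseline) with programs strong enough that recovery failures indicate
implementation defects rather than sampling luck. The `null` fixture
(2000 cells × 500 genes, fold 1) provides pure noise for calibration; the
`tiny` fixture (2 × 20 × 50, peak mode) exercises mechanics quickly.

A `structure_seed` separates the marker-assignment RNG from count
sampling, so replicates of one population share their planted programs
while redrawing noise — this is what makes build-on-one-replicate,
score-on-another experiments meaningful. Under the null the planted sets
carry unit weights (the generative log2 fold of 0 would be an invalid
weight).

In peak mode every gene receives 1–3 peaks placed wholly inside its
window on a synthetic chromosome with non-overlapping windows, and each
cell's gene count is split multinomially (equal probabilities) among the
gene's peaks, so projecting the peak matrix back through the default
windows reproduces the activity matrix exactly — a strict round-trip used
in the tests.

The simulator does **not** emulate: fragment-level ATAC structure,
Tn5 insertion bias, per-cell library-size variation beyond NB sampling,
batch effects, doublets, correlated gene programs, or peaks shared
between genes. Passing benchmarks therefore demonstrates correctness of
the pipeline's computations and its statistical calibration under a
clean generative model — not annotation accuracy on real tissue, where
projection noise and reference quality dominate.

## Problem sizes and numerical notes

The test suite and `scripts/acceptance.py` run the benchmark conditions
(600 cells × 2000 genes, 1000-cell permutation nulls, 10⁶ random pairs
for score-combination bounds, 100-instance brute-force cross-checks for
the overlap and gating oracles); the whole suite completes in well under
a minute on one CPU. Other constants: variance floor 1e−8; gamma fit
requires ≥100 null values with positive variance; scale clipping ±10;
Wilcoxon exact branch for min group size ≤ 8; duplicate matrix
identifiers are suffixed `.1, .2, …` rather than dropped, preserving
matrix shape. Known limitations mirror the method's scope: signatures
must cover the cell types present (no novel-type discovery), peaks far
from any gene window are ignored, and annotation quality of the reference
bounds signature quality.
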