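# Methods

## Model and procedure

The pipeline treats a log2 gene-by-sample expression matrix as the unit of
analysis. Four stages:

1. **Quantile normalization.** Each column (array) is replaced by the
   across-column rank means: sort every column, average the sorted vectors
   position-wise to obtain the target distribution, and map each value back
   through its within-column rank. Ties receive average ranks and are
   resolved by linear interpolation between neighbouring target values, so
   the transform is deterministic. For tie-free columns the operation is
   exactly idempotent and all columns share one multiset of values
   afterwards; with ties, tied entries receive interpolated values and the
   column multisets can differ microscopically — an accepted property of
   average-rank tie handling. Probe-level background correction and CEL
   parsing are out of scope: the input is already a summarized numeric
   matrix.

2. **Per-gene ANOVA.** Classical fixed-effects ANOVA on each gene's log2
   values. With one factor this is one-way ANOVA; with two crossed factors,
   main effects plus the interaction whenever every cell is replicated.
   Balanced designs are computed by the textbook sums-of-squares
   decomposition, vectorized across genes (this is what makes
   5000-gene × 200-replicate power studies cheap); unbalanced designs fall
   back to per-gene Type-II ANOVA via statsmodels, omitting the interaction
   (with a logged warning) when a cell is empty. The p-value that feeds the
   DE filter is always the primary factor's main effect — the second factor
   and the interaction are reported but do not gate significance, because
   the contrast of interest in a disease-vs-control design is the genotype
   main effect. Genes with (numerically) zero residual variance are flagged
   degenerate, get `NA` p-values, and can never be called significant;
   this avoids spurious infinite F statistics.

3. **Signed fold-change filter.** The fold change between the contrast's
   two levels is reported in the signed convention (ratio if ≥ 1, negative
   reciprocal otherwise), the standard output format of microarray analysis
   suites; it is the only convention consistent with published tables in
   which no magnitude is below 1. The filter retains genes with
   p < `p_cutoff` (default 0.05) and |FC| > `fc_cutoff` (default 1.5),
   both strict, so boundary values are excluded; the magnitude criterion is
   symmetric in direction. Everything else is `NA` in the exported table —
   `NA` means "did not pass the filter", not "not measured".

4. **Hypergeometric over-representation.** With universe size N, pathway
   size M (after restricting to the universe), DE-list size n, and overlap
   k, the enrichment p-value is the upper tail P(X ≥ k). A `"literal"`
   mode computing the partial lower sum Σ_{x=1..k} pmf(x) is provided for
   transparency because the formula is sometimes printed that way, but that
   quantity is a lower-tail sum: it approaches 1 − pmf(0) for strongly
   enriched overlaps and cannot produce small over-representation
   p-values, so the upper tail is the default and the only mode used by
   the pipeline. Probabilities come from scipy's log-gamma-based
   hypergeometric functions, stable at the 1e−14 magnitudes strong
   enrichment produces, and are clipped into (0, 1] (floored at the
   smallest positive double). Significance uses a fixed cutoff, default
   1e−4, with an optional α/#pathways Bonferroni policy.

## Comparative stage

Venn counts are exclusive-region sizes over 2–3 retained-gene sets (more
than 3 sets is rejected — the diagram semantics stop being well defined).
Reversal classification is purely sign-based on the two filtered tables: no
magnitude threshold is re-applied, because the tables already encode the
filter. Genes present in only one contrast's universe are treated as `NA`
in the other and flagged (`in_both_universes`) rather than dropped.
Pathway direction summaries count up / down / `NA` members of each
universe-restricted pathway and label the majority direction among retained
members ("tied" when equal, "none" when no member is retained).

## Synthetic data

`generate_dataset` emulates normalized two-group microarray data: values
are baseline + group shift + i.i.d. Gaussian noise on the log2 scale, with
homoscedastic gene-level SD. Defaults: 3 replicates per group (the usual
small-animal design), baseline 8.0 log2 units (mid-range intensity for a
normalized array), noise SD 0.3 (a typical residual SD for normalized
expression data), DE fraction 5%, and a 1.0 log2 (two-fold) shift of random
sign for DE genes. Pathway spikes force a stated fraction of a pathway's
members to be DE for power studies. Under this model the per-gene ANOVA is
exact, which is the point: calibration failures then indicate
implementation errors, not model mismatch. What the generator deliberately
does not emulate: probe-level intensity distributions, array batch or
spatial artifacts, correlated genes, and heavy-tailed or
intensity-dependent noise — so passing calibration here shows the
statistics are computed correctly, not that real arrays satisfy the
model's assumptions.

`matrix_from_gene_table` encodes a published table of signed fold changes
into a calibrated matrix: each non-NA value becomes an exact log2
group-mean shift, NA genes get zero shift. A strictly noiseless matrix
would have zero residual variance everywhere, making every gene degenerate
and the filter empty; instead a small deterministic within-group offset
pattern (default magnitude 1e−3, summing to zero within each group) is
added. Group means — hence recovered fold changes — are untouched to
floating-point accuracy, while the residual variance is positive and equal
across genes, so every non-NA gene is recovered significantly and every NA
gene shows FC = +1 with p ≈ 1. With the default jitter, fold changes as
small as the 1.5 filter boundary are recovered with F statistics orders of
magnitude beyond any reasonable cutoff, and the choice of jitter magnitude
is immaterial across several orders of magnitude.

## Numerical choices

- Gene symbols are uppercased everywhere on ingestion (published tables mix
  human and mouse casing); duplicates after uppercasing are rejected.
- Degeneracy threshold: residual SS ≤ 1e−18 counts as zero variance —
  far below the ~4e−6 residual SS the calibrated-matrix jitter produces,
  far above accumulation error for constant genes.
- Enrichment results are sorted by ascending p-value with the pathway name
  as a deterministic tiebreak.
- Pathway members and DE genes outside the universe are dropped (with a
  logged count) before counting, so every hypergeometric count is
  consistent with its own N.
- The empty DE list is handled without special-casing: n = 0 gives k = 0
  and an upper-tail p of exactly 1 for every pathway (a warning is logged).

## Problem sizes used in validation

The test-suite and acceptance-script simulations use 2000-gene universes
with 200 random pathways (sizes 20–120) and 2000 pathway tests for null
calibration, 2000 genes for estimator-recovery and p-value-uniformity
checks, and 100 replicates of a 5000-gene dataset with an 80%-spiked
pathway for power; the exact hypergeometric cross-check enumerates every
count configuration up to N = 25 in the tests (N = 20 in the acceptance
script). These sizes give binomial/KS noise well inside the asserted
envelopes while keeping a full run in the tens of seconds.

## Known limitations

- The published pathway-level enrichment p-values shipped as a fixture
  cannot be recomputed from packaged data: the underlying genome-wide DE
  lists and the 2014 pathway annotation snapshot were never deposited. They
  are used only for cutoff-separation and magnitude sanity checks. One cell
  of that table is internally inconsistent in the source (a pathway narrated
  as significant prints p = 6.9e−3, above the stated 1e−4 cutoff); the
  checks cover the consistent cells.
- Two-way ANOVA assumes homoscedastic Gaussian residuals per gene; no
  moderated/empirical-Bayes variance shrinkage is provided (deliberately —
  the pipeline reproduces a plain-ANOVA workflow).
- The unbalanced-design path loops genes through statsmodels and is two to
  three orders of magnitude slower than the balanced path.
- Hypergeometric p-values are discrete and therefore conservative: the null
  false-positive rate at α sits visibly below α for realistic pathway
  sizes.
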