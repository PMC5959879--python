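# Methods

This note documents the models and procedures `immunorank` implements, the
conventions chosen where the design was genuinely open, and what the
synthetic generators do and do not emulate.

## Data model and conventions

Expression matrices are gene × sample grids of nonnegative normalized
values (RSEM-scale for RNA-seq cohorts, RMA-scale for arrays) with dual
gene identifiers (`SYMBOL|ENTREZ`).  Missing cells are distinct from
zeros: a zero is a valid measurement; missingness arises only from
explicit NA tokens at read time or from the log transform downstream
(log2 of zero → NaN, the convention of the legacy clustering/heat-map
tools).  Duplicate gene rows are kept at read time; collapsing is an
explicit operation used only for the array and cross-species steps.
Files are UTF-8, decimal-point TSV; clinical readers accept a
configurable column-name map because clinical dialects vary.

## Survival preprocessing

From the four raw fields (days to death, days to last follow-up, days to
last known alive, vital status) the cleaning rules are: discard records
with a negative follow-up (unrepairable conflict, returned separately);
event = 1 iff the vital label is "dead"; dead → survival days = days to
death; alive → the maximum of the present follow-up fields; years =
days/365.  An alive record with a positive death date is an internal
conflict: it is flagged and resolved to the vital label by default, with a
per-sample override hook, because manual curation against external
registries is not a reproducible computation.

## Survival statistics

Group comparisons use the log-rank (Mantel–Cox) test with df = k − 1.
Expression-based splits are inclusive at the median (value ≥ median →
high), so all split-based effects depend on ranks only and are invariant
under strictly increasing transforms.  Hazard ratios come from a
univariate Cox proportional-hazards fit on the binary indicator.  Tie
handling defaults to the Efron approximation (the stricter standard;
Breslow is available behind a switch, since the original fitting routine's
tie convention is not documented).  The 95% CI is Wald on the log-HR
scale.  The batch screen applies the median-split effect per gene and
corrects the log-rank p-values with Benjamini–Hochberg across the batch;
genes with constant expression are flagged untestable and excluded from
the correction.

## Subtype assignment and aggregation

Samples are assigned to the four squamous expression subtypes (Classical,
Basal, Primitive, Secretory) by Pearson correlation against published
predictor centroids after per-gene log2 transform (zeros → missing) and
median centering, over the genes shared with the centroid table (matched
by symbol, falling back to Entrez).  Correlations run over pairwise-
complete entries; ties in the argmax break by the fixed subtype order;
samples with under two usable genes are unassignable.

Aggregation computes per-subtype mean vectors over all genes and the six
pairwise Pearson coefficients, then pairs the subtypes greedily: the
global best pair first, the remaining two forced.  Greedy matches the
stepwise description of the procedure; a brute-force max-weight matching
over the three possible pairings is computed alongside and a
disagreement, which is possible on adversarial inputs, is flagged and
warned rather than silently resolved.  Display order puts the two
most-populous subtypes at the heat-map flanks with each aggregate
contiguous.

## Gene-selection cascade

A gene survives the hybrid cascade between two sample groups when all five
criteria hold:

- **(a)** relative variation of the group medians,
  (max − min)/(min + ε) with machine double ε, strictly in the top 50% of
  all genes;
- **(b)** two-sided Wilcoxon rank-sum p "calculable" (not the degenerate
  all-identical case) and < 0.01, restricted to genes present (value
  ≥ 0.5) in more than 60% of all samples;
- **(c)** Storey q-value over the criterion-(b) p-value pool < 0.01;
- **(d)** overall median strictly above the first octile
  (12.5th-percentile order statistic, nearest-rank lower convention) of
  all gene medians;
- **(e)** standard deviation strictly in the top 50% (the gene-ontology
  variant e′ tightens this to the top 1/3 of the original universe, so
  the variant selection is always a subset).

"Strictly in the top fraction f" is implemented as strictly greater than
the largest order statistic excluded from the top ⌊f·m⌋, so boundary ties
fail — the strictness is deliberate and matches the bottom-1/8 trimming
rule used before gene-set export (mean, SD, or presence count strictly in
the lowest 1/8 each computed on the full input).  The Wilcoxon test is
exact for groups of ≤ 20 without ties and a continuity-corrected normal
approximation otherwise.  The presence filter counts values ≥ 0.5 on the
raw normalized scale, before any transform.

Storey's π0 is estimated by the smoother method: π0(λ) over
λ ∈ {0.05, …, 0.95}, smoothed with a 3-degree-of-freedom least-squares
fit and evaluated at the largest λ, clipped to (0, 1].  q-values are the
π0-scaled step-up, monotone in p, and never exceed the BH-adjusted values
when π0 ≤ 1.

## Matrix structure

The display transform is log2 (zeros → missing) with per-gene mean or
median centering.  Hierarchical ordering uses uncentered correlation
(cosine about zero) over pairwise-complete entries with average linkage —
the convention of the classic clustering tools — returning the dendrogram
leaf order; items with no overlap against all others are placed last with
a warning.  Genomic dissimilarity between subtypes is the city-block (L1)
distance between per-gene subtype mean vectors; the 4×4 distance matrix
satisfies the metric axioms by construction and the maximal pair
identifies the most divergent subtypes.

Two splitting rules cut an ordered matrix into upper and lower portions:

- **Δ(CB, PS) scan** — per gene, the fraction of each subtype's samples
  at or above the gene mean ("hyper-expression", inclusive ≥); Δ =
  mean(%C, %B) − mean(%P, %S).  Within a scan window the maximal prefix
  with Δ < 0 is located, tolerating interior violation runs of at most 3
  consecutive genes (runs reset after each Δ < 0 gene; a longer run ends
  the prefix at its start).  The split index is the first gene of the
  positive regime.  Window and tolerance are parameters because their
  published values are dataset-specific.
- **Splitting point** — in a sequence of signed per-gene averages, the
  first flip away from the opening sign regime that persists for at least
  five following couples of consecutive values (six elements of the new
  sign); a flip that reverts sooner is ignored and the original regime
  resumes.  Zeros match neither sign.

## Cohort statistics

Correlation significance uses t\* = r·√(n−2)/√(1−r²) on n − 2 df, with r
computed on untransformed values and a Spearman pair reported as
confirmation.  Subtype comparisons use one-way ANOVA on log-transformed
values with two homoscedasticity companions — Brown–Forsythe (median-
centered Levene, threshold 0.05) and the max/min variance ratio (cutoff
configurable, default 3, since the textbook criterion is cited without a
number) — plus Kruskal–Wallis as a rank-based check.  Enrichment of
samples above/below a cohort median uses the exact two-tailed binomial
test (minimum-likelihood convention) with BH correction across groups.

## Immune scoring

Signature assembly merges marker additions into a base list, matches genes
to the expression universe by Entrez id (symbol fallback for genes without
one), discards unmatched genes and rejects any gene that would belong to
three or more cell types; one or two types per gene is an invariant of the
signature container.  Density scoring and CD14 scores are as described in
the README; dual-type genes contribute with full weight to both types, and
the single possible tie at the CD14 median is handled by the generic
≥-median rule with no special-casing.  Cell-type correlation structure is
the Spearman matrix over density-score columns, hierarchically ordered on
its raw values (no transformation or centering) with the same
uncentered-correlation/average-linkage engine; the color scale bounds are
the matrix min/max.

## Mouse gradient patterns

For the (4, 3, 3) replicate design (normal → primary → metastatic), a gene
is differential between two groups when (a) every replicate of one group
strictly exceeds every replicate of the other (implied p = 1/C(n1+n2, n2)
under exchangeability, verified by enumeration); (b) the relative
difference of group means is ≥ 50% — measured against the smaller mean,
consistent with the relative-variation convention of the selection
cascade; the baseline is configurable because it is genuinely
under-specified, and nonpositive means make the criterion indeterminate;
and (c) the gene's range is strictly in the top 75% genome-wide.  The
gradient patterns A-1/A-2 (rising) and B-1/B-2 (falling) are evaluated
literally from their requirement lists; the two families are mutually
exclusive by construction while sub-patterns within a family may co-occur.
A gene is selected when it is differential against at least one tumor
condition and follows pattern A or B.  Probe collapsing keeps, per
repeated symbol, one row of an identical set or the highest-SD row, and
drops symbol-less probes.  Cross-species matching maps selected mouse
genes through an explicit ortholog table and keeps human genes present in
more than 60% of the two extreme subtypes' samples with Wilcoxon BH-FDR
below 5 × 10⁻⁵, split by the median-expression ratio of those subtypes.

## Synthetic generators

All generators are pure functions of their parameters and seed.  Noise is
log-normal (Gaussian on the log2 scale) because the pipeline consumes
normalized expression values, not counts.  The cohort generator plants
four subtype centroids with per-gene standard-normal profiles, samples at
noise sd 0.5 by default, and zeroes a small fraction of entries to
exercise the zero → missing path; its centroid table is centered the same
way the assignment transform centers the cohort, so a noiseless sample
correlates exactly 1 with its own centroid.  The survival generator uses
exponential event times with the hazard multiplied by the planted HR for
marker-high samples and independent exponential censoring.  The signature
generator gives each cell type a latent per-sample activity shared by its
markers and couples one module to a CD14-like gene with adjustable
strength; the mouse-array generator plants monotone condition means of a
chosen gap over i.i.d. noise.

What the generators do **not** emulate: library-size or batch effects,
count-level noise (negative binomial), gene-gene correlation beyond the
planted modules, non-proportional hazards, or the full 20,531-gene
universe of a real cohort.  Passing recovery tests therefore demonstrate
correctness of the algorithms under the stated statistical structure, not
robustness to every artifact of real data.

## Problem sizes and tolerances

The test suite and the acceptance script run planted-truth simulations at
moderate sizes chosen to give stable recovery rates: hazard-ratio recovery
at n = 400 over 50 seeds (expected within [1.6, 2.5] in ≥ 90%), subtype
recovery at 500 samples × 200 genes (≥ 95% labels), CD14-rank recovery at
200 samples over 50 seeds (rank 9 in ≥ 95%), and the null calibration of
the batch screen at 100 genes × 200 samples (false-positive count inside
the 99% binomial band around 5%).  Numerical tolerances: rank-sum
conservation is asserted exactly (to 1e−12); centering residuals to 1e−9;
Cox-fit comparisons to the fit tolerance (relative 1e−9 for identical
inputs, 5% for inverted-label equivalence).

## Known limitations

- The batch screen is univariate; no stage-adjusted or multivariate Cox
  models (stage subgroups are handled by filtering the clinical table).
- Enrichment analysis itself (DAVID/EASE, GSEA, pathway tools) is
  external; the package only prepares their inputs (GCT/CLS, trimmed
  matrices, class files) and filters their output tables.
- The packaged signature file is synthetic: it reproduces the composition
  of curated immunome compendia (598 genes, 572 single-type, 26 dual-type,
  29 cell types) with synthetic identifiers, for exercising the reader and
  composition checks without redistributing curated data.
- No CEL/RMA processing and no cohort download clients; normalized
  matrices are consumed as given.
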