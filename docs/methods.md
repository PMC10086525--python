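# Methods

`agesig` implements a cross-strain, cross-tissue analysis of immune aging at
desk scale: it asks which genes (or chromatin-accessibility peaks) change
with age *consistently* across mouse strains and tissues, and attributes the
signal with rank aggregation, enrichment statistics, variance decomposition,
and footprint-level regulatory summaries. Because the real study requires
terabyte-scale reprocessing, the package ships a synthetic-data generator
whose structure matches the study design; all quantitative claims the test
suite makes are claims about recovery of planted truth under that generator.

## Age-association model

Within one (strain, tissue) stratum, counts for feature *g* in sample *i*
follow a negative-binomial GLM with log link:

    log mu_gi = log(N_i * f_i) + b_g0 + b_g,age * age_i + b_g,sex * sex_i

where `N_i` is the library size and `f_i` the TMM scaling factor. Age in
months is continuous; the reported `log2fc_span` is `b_age * (age_max -
age_min) / ln 2`, i.e. the log2 fold change over the whole sampled age span,
which makes the continuous fit comparable to an old-vs-young contrast.

Dispersion is estimated per feature by method of moments on the residuals of
an initial Poisson fit (`phi = sum[(y - mu)^2 - mu] / sum mu^2`, with a
small-sample df correction), floored at 1e-8, and shrunk 50/50 toward the
median dispersion across features. This is intentionally simpler than
empirical-Bayes tagwise machinery; it is stable at n = 12 per stratum and
its operating characteristics are verified by simulation rather than by
numeric identity with any reference tool.

The age coefficient is tested with a Wald statistic referred to a
t-distribution with n − p degrees of freedom. At n = 12 the normal reference
is visibly anticonservative (empirical type-I error ≈ 0.08 at nominal 0.05 in
our null simulations) while the t reference is close to nominal (≈ 0.043);
the t reference is therefore the default. Non-converged fits are flagged and
assigned p = 1. All fitting is a batched IRLS vectorized across features;
a 5000-gene stratum fits in well under a second, and the implementation is
cross-checked against statsmodels' NB GLM on small cases in the test suite.

Filtering follows the CPM rule: features must reach CPM ≥ 2 (log2 CPM ≥ 1)
in at least 2 samples. The log base of the threshold is exposed because the
rule is sometimes stated in natural logs. TMM factors implement the published
trimmed-mean-of-M-values algorithm (75th-percentile reference selection, 30%
M-trim, 5% A-trim, precision weighting, geometric-mean-1 rescaling) and are
verified against edgeR's `calcNormFactors` output frozen into the tests.

Features are called differential at BH fdr < 0.05 **and** |log2fc_span| > 1,
both strict.

## MAG conservation score

For gene *g* in tissue *t* with per-strain significance ranks `r_{g,s,t}`
(rank 1 = smallest p; ties broken by larger |log2fc|, then gene id):

    m_{g,t} = (prod_s 1 / r_{g,s,t})^(1/S)
    M_g     = sum_t m_{g,t}

Genes filtered out of a stratum get rank `n_tested + 1` there, so a gene
expressed in only one strain is penalized rather than dropped. The score is
direction-blind; a consensus direction (+1/−1 when the fold-change sign
agrees in every stratum where the gene was tested) is reported alongside.
The implementation is generalized to S strains and T tissues and is checked
against a brute-force evaluation of the formula to 1e-12.

## Preranked GSEA

The MAG-descending gene list is walked; set members add `|M_g|^w` (normalized
over the set, default w = 1), non-members subtract `1/(N − n_set)`. The
enrichment score is the maximum of the running sum; because weights are
normalized the walk ends at exactly 0, so ES ∈ [0, 1] and "no enrichment at
the top" yields ES near 0 rather than a negative value. The null permutes
gene labels (uniform placement of the set's positions); p uses the add-one
rule `(1 + #{null ES ≥ ES}) / (1 + n_perm)`, and NES divides ES by the mean
of the strictly positive null ES values. When `C(N, n_set) ≤ 1e5` an
exhaustive mode enumerates every placement instead; the Monte-Carlo p then
converges to the enumeration tail frequency (the two add-one formulas differ
by O(1/#placements), which matters only for toy list sizes). The leading
edge is the set members at or before the running-sum maximum.

## Over-representation tests

Module enrichment is the hypergeometric upper tail P(X ≥ k) for an n-gene
query against a K-gene module in an N-gene universe, BH-adjusted across the
collection, enriched at fdr < 0.05. The universe defaults to the stratum's
expressed (tested) genes and is overridable. Only over-representation is
tested. The Wilcoxon rank-sum utility is exact (enumeration) when the
smaller sample has ≤ 10 tie-free observations and otherwise uses the normal
approximation with midranks and tie correction.

## PVCA

Features are centered and scaled, the sample-sample covariance is
eigendecomposed, and the smallest number of PCs whose cumulative variance
reaches 0.6 (at least 3) is retained — the retention defaults follow the
method's reference implementation. For each retained PC a random-intercept
model with one variance component per factor is fit by REML (statsmodels
MixedLM); a REML fit whose components do not roughly reproduce the PC's
variance (a failure mode on degenerate, noise-free scores) falls back to a
non-negative balanced-design method-of-moments estimator.

Aggregation across PCs sums the **absolute** variance components and
normalizes, crediting unretained eigenvalue mass to the residual. We do not
average eigenvalue-weighted per-PC *proportions*: realized level contrasts
shrink a factor's eigenvalue mass by (L−1)/L for an L-level factor and the
residual hides almost entirely in the discarded PCs, so proportion averaging
systematically over-credits few-level factors and zeroes the residual. The
REML components are unbiased for the generative variances, and summing them
recovers the planted fractions within ±0.10 in 19/20 seeds at the default
recovery conditions (500 features, 24 samples, fractions 0.6/0.3/0.1).
Factors are categorical (age included); main effects only, matching the
factors the study reports.

## Regulatory statistics

All intervals are 0-based half-open; book-ended intervals do not merge.
Consensus peaks merge per-sample intervals overlapping by ≥ 1 bp and keep
regions supported by ≥ 2 distinct samples. Peaks are annotated to the gene
with the nearest TSS (center-to-TSS distance, strand-signed, ties to the
smaller gene id) and flagged as promoter peaks within ±2 kb.

Footprints are filtered at purity > 0.9 (strict). TF enrichment in
opening/closing peaks is a bias-naive hypergeometric test on binary
peak-contains-footprint indicators against age-stable background peaks, BH
per direction; the published method this replaces additionally corrects for
read-count and GC bias, which requires read-level data that is out of scope
here — results on real data would need that correction. A TF is reported
pan-stratum when q < 0.05 in ≥ 2 strata (the stratum is our pooled unit of
analysis). Footprint proportions normalize per-group TF counts by the group
total; locus counts tally footprints overlapping ±100 kb around a gene's
TSS; aggregate cut profiles average per-base cut counts in ±100 bp windows
around footprint centers and divide by the group's total cut count.

## Cell-composition trends

Per cell type and stratum, percent is regressed on age in months by OLS; the
slope (percent per month) gets a two-sided t-test and BH correction across
cell types within the stratum. Percentages are fit raw (no arcsine/logit),
and sibling cell types are modeled independently. Zero-residual fits return
the exact slope with p marked unavailable.

## Synthetic-data generator

`generate_study` draws NB counts with mean `lib_i * 2^(b_g + f(age) *
log2fc_g) / 1e6`, where `b_g ~ Uniform(0, 9)` is the baseline log2 CPM
(spanning filtered-out to highly expressed), `f(age)` is the fractional
position of the age in the min→max span (so planted log2 fold changes are
old-vs-young effects, per-month slopes being derived), library sizes are
uniform on [0.8, 1.2] million, and per-gene dispersions are Gamma(shape 2,
mean 0.1) unless fixed. Defaults: 2 strains × 4 tissues, ages 3 and 18
months, 5 replicates per age, a 5-gene conserved signature planted at
log2fc 2 — the shape of the study the package targets.

`generate_regulatory` lays non-overlapping peak regions on a single
synthetic chromosome (default 10 Mb), jitters per-sample intervals, labels
10% of regions opening and 10% closing, and draws footprints per pooled
(strain, tissue, age) group. In old groups each designated aging TF's
sampling share is multiplied by its configured factor (the remainder spread
over the rest, so the old/young share ratio equals the multiplier exactly)
and its footprints land inside opening regions with probability 0.9. Purity
scores are Beta(8, 2), making the 0.9 filter non-trivial. Cut-site signal is
Poisson background (rate 0.2/bp) plus Gaussian-shaped enrichment (amplitude
3, sd 15 bp) at footprint centers, generated for a configurable subset of
strata to bound memory.

`generate_variance_dataset` defaults to a balanced 3-level × 2-level design
with 4 replicates (24 samples): a tissue-like and a strain-like factor. The
level counts were chosen so the factor structure spans exactly the retained
PCs under the default retention rule; with 2-level-only designs the single
realized contrast per feature makes per-feature variance shares so skewed
that no PC-based estimator attributes them reliably.

`generate_composition` draws per-animal percentages as intercept + slope ×
age + Gaussian noise clipped to [0, 100], with default trends (naive CD8
−1.2 %/month, memory CD8 +1.0, B −0.3, monocytes +0.5) mirroring the
direction and rough magnitude of known aging shifts.

What the generator does **not** emulate: sequence content, GC/mappability
structure, gene-gene correlation, batch effects, compositional coupling of
cell-type percentages, and read-level artifacts. Passing recovery tests
therefore demonstrates correctness of the statistics under the stated
model, not robustness to those real-data complications.

## Problem sizes and reproducibility

The defaults used by the pipeline and the test suite (2000–5000 genes, 12
samples per stratum, 400–1000 peak regions, 10 000 GSEA permutations, 20
recovery seeds) were chosen as the smallest designs at which the planted
effects are comfortably identifiable. Every stochastic stage takes an
explicit seed; identical configs and seeds reproduce byte-identical outputs,
which the pipeline verifies by hashing every written table into its run
manifest.

## Known limitations

* The dispersion estimator is deliberately simple; very low counts with few
  replicates can under-estimate dispersion despite the median shrinkage.
* The footprint enrichment is bias-naive (see above).
* PVCA models main effects only; interaction variance shows up as residual.
* MAG treats ranks from strata with different numbers of tested genes as
  exchangeable; the worst-plus-one convention penalizes but does not model
  missingness.
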