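# Methods

This note documents the models and procedures implemented in
`immunoprofiler`, the assumptions behind them, and the choices made where
the design was genuinely open.

## QC and normalization

Per-sample quality is gated on the geometric mean of the five housekeeping
probes (DDX50, EIF2B4, MRPS5, SAP130, TLK2). A sample is excluded when that
geometric mean falls **below** the threshold (default 100 counts); a sample
exactly at the threshold passes. Counts are floored at 1 (configurable)
before any geometric mean or logarithm: nCounter counts of zero occur for
low-expressed probes, the flooring avoids −∞, and at the count scales where
QC and normalization operate (10²–10⁴) the floor is numerically irrelevant.

Normalization is sequential and cohort-wise. For a reference probe set
(positive controls first, then housekeeping genes), each sample's reference
geometric mean `geomean_s` is computed, then the cohort geometric mean of
those values (`geomean_geomeans`), and every count of sample *s* is
multiplied by `f_s = geomean_geomeans / geomean_s`. Both factor vectors are
retained as provenance. Two consequences worth knowing:

* After each stage the reference-probe geometric mean is identical across
  samples (exactly, up to floating point).
* Because `geomean_geomeans` is a cohort quantity, rescaling one of *n*
  samples by λ rescales the whole normalized cohort by the common factor
  λ^(1/n). Between-sample structure (every ratio, every log-difference, all
  downstream scores up to a shared constant) is exactly invariant, but the
  absolute level is batch-dependent — which is why the batch composition is
  part of the provenance, and why scores from different normalization
  batches should be compared only against each batch's own reference
  samples.

No background subtraction from negative probes is performed, and probes are
never imputed or dropped per-lane.

## Tumor inflammation signature (TIS) and linear scores

TIS is the weighted sum of log2-transformed normalized counts over 18 genes
covering antigen presentation (PSMB10, HLA-DQA1, HLA-DRB1, CMKLR1), T/NK
abundance (HLA-E, NKG7, CD8A), interferon activity (CCL5, CXCL9, CD27,
CXCR6, IDO1, STAT1) and T-cell exhaustion (TIGIT, LAG3, CD274, PDCD1LG2,
CD276): `score_s = Σ_g w_g · log2(count_gs)`. The weight file shipped in
`immunoprofiler/data/tis_weights.csv` was transcribed from the public
patent filing that defines the signature (the defining papers do not print
the weights); all weights are positive except CD276 (−0.0239). The file
path is configurable so alternative weightings can be substituted; a
unit-weight fallback exists but is flagged in the signature metadata so it
can never silently stand in for the published weighting.

PROGENy-style pathway scores use the same linear-score machinery with a
user-supplied coefficient matrix on per-gene z-scored expression; the
coefficients are treated as external data and never re-derived.

Missing signature genes are a hard error — no silent subsetting — because a
closed 103-gene panel either carries a gene or the signature is invalid.

## GSVA

`gsva_score` natively implements gene-set variation analysis: per-gene
Gaussian-kernel CDF estimation across samples (bandwidth s_i/4), sample-wise
rank normalization into the symmetric statistic |p/2 − rank| (up-weighting
both expression extremes), a weighted Kolmogorov–Smirnov random walk down
the per-sample gene ranking (weight exponent τ = 1), and the "maxdiff"
enrichment score: largest positive plus largest negative deviation of the
walk. At least 3 samples are required (the kernel CDF is estimated across
samples); a set with no genes in the matrix is an error, and partial
intersections are used as is. Scores are invariant to gene order and
equivariant under sample permutation. The implementation is validated
against an independent literal-loop reimplementation of the same equations
(agreement to 1e-8 on matrices up to 20×10), not against fixed reference
values, since published GSVA output varies with version and options.

## Consensus clustering

Monti-style subsampled consensus: for each candidate k, repeatedly draw a
fraction of samples (default 0.8, 1000 resamples; tests and presets use
fewer), cluster the subsample by average-linkage hierarchical clustering on
the Pearson-correlation distance d = 1 − r, and accumulate pairwise
co-clustering over co-sampling counts. The consensus matrix is re-clustered
(same linkage) for the final assignment. Average linkage for both the inner
and final clustering is the conventional default; it is configurable.

k is selected by the relative delta-area criterion on the consensus-CDF
area: the chosen k is the largest k whose relative area increase stays
above a threshold (default 0.1). A low-confidence flag is raised when the
mean within-cluster minus between-cluster consensus gap at the chosen k
falls below 0.5 — on structureless i.i.d. input, subsampled clustering is
unstable and the gap collapses, whereas planted structure keeps it near 1.
All diagnostics (consensus matrices, CDFs, areas, gaps) are retained for
manual review, mirroring how consensus clustering is used in practice.

PCA projection is a column-centered SVD with a deterministic sign
convention (largest-magnitude loading positive per component). UMAP is
deliberately not implemented (non-deterministic embedding; PCA covers the
diagnostic need).

## Differential expression

Per-gene two-group t-tests on log2 expression with Benjamini–Hochberg
correction. Welch (unequal variance) is the default; the pooled-variance
variant is available since row-wise t-test implementations in common use
default to it. Genes with zero variance in both groups report t = 0, p = 1
rather than NaN. log2FC is mean(A) − mean(B) on the log2 scale. Output is
sorted by q, then |log2FC|.

## Survival analysis and cutpoint selection

Kaplan–Meier curves and Cox proportional-hazards fits go through lifelines
(Efron tie handling, convergence tolerance on the partial likelihood); the
log-rank test is implemented natively with the exact hypergeometric
variance under ties, because the cutpoint scan evaluates it at every
admissible split and needs a fast vectorizable form. The native statistic
is cross-checked against both lifelines and a brute-force per-event-time
accumulation in the tests.

`optimal_cutoff` dichotomizes a continuous score at the value maximizing
the standardized two-group log-rank statistic, subject to both groups
holding at least `minprop` (default 0.1) of the cohort. Because the
cutpoint is chosen to maximize the statistic, the naive log-rank p at the
chosen cutpoint is strongly anti-conservative. The reported p-value is
therefore the improved-Bonferroni approximation for maximally selected rank
statistics (Miller–Siegmund/Lausen–Schumacher),

    P(max |Z| > b) ≈ φ(b)(b − 1/b)·log[ε₂(1−ε₁)/(ε₁(1−ε₂))] + 4φ(b)/b,

with ε₁ = minprop, ε₂ = 1 − minprop, which is approximately uniform under
the null (verified by simulation in the tests). The raw unadjusted p is
stored alongside.

`bootstrap_cutoff_p` repeats the selection on subsamples without
replacement (default 1000 draws of 90%), records each replicate's adjusted
p, and summarizes by the **median** — the aggregation is a package choice
(robust, order-statistic-stable); the full replicate distribution is always
returned so any other summary can be recomputed. Replicates with no
admissible cutpoint are skipped; more than 10% skipped is an error.

A known property of maximally selected cutpoints, visible in the recovery
simulations: near the optimum the statistic process is locally
drift-free, so the selected cutpoint wanders a few samples into the
adjacent population even under a strong step hazard (HR = 3, n = 120).
Recovery is therefore assessed as the cutoff landing within one
inter-population score-gap width of the planted threshold, not as an exact
gap hit, which no estimator of this family achieves reliably at that effect
size.

Composite stratification uses strict inequalities — TIS > 9 and
TMB > 100 SNV/Mb define "high" — so samples exactly at a cutoff are low.
Quartile stratification uses linear-interpolation (type-7) quantiles; group
boundaries depend on this definition, hence it is fixed and documented.

## Tumor mutation burden

Variant tables arrive pre-annotated (caller, dbSNP, ClinVar, Cancer Gene
Census flags are inputs, never computed). The somatic filter keeps
quality-passing variants with VAF ≥ 0.05 (inclusive) that are not common
SNPs. TMB = (number of single-nucleotide variants) / callable megabases
(default ~50 Mb); indels are excluded from the numerator and reported
separately. Classes: ultra-hypermutant strictly above 100 SNV/Mb,
hypermutant 10–100 inclusive, non-hypermutant below 10. The impactful-variant
filter (coding/splice consequence, not ClinVar (likely-)benign, CGC-listed)
is independent of and commutes with the somatic filter.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
real biology:

* **Technical structure** — a lognormal lane efficiency (sd 0.2) multiplies
  every probe; a lognormal RNA-content factor (sd 0.35) multiplies
  housekeeping and endogenous probes; positive controls follow the standard
  ladder (128…0.125 fM, 60 counts/fM) times lane efficiency. Positive-control
  normalization removes the first factor, housekeeping normalization the
  second — so the generator poses exactly the problem the two-stage scheme
  solves.
* **Biology** — one latent infiltration level z per sample (group-specific
  mean/sd) drives all immune genes: counts are negative-binomial with mean
  `scale · 2^(a_g + β_g z)`. Dispersion defaults to 0.01 (nCounter counting
  is near-Poisson; biological covariation enters through the latent factor,
  which is the single-factor simplification this generator deliberately
  makes). Signature-gene baselines and loadings are jittered but projected
  so that a sample's expected TIS is exactly 7.66 + 0.736·z; group latent
  means in the presets are solved from the group median scores they emulate.
* **QC failures** — an exact planted count of degraded samples whose
  RNA-derived counts are suppressed 20-fold, putting their housekeeping
  geomean far below threshold.
* **Survival** — exponential event times with hazard log-linear in the
  expected score, a step at a threshold, or looked up per TIS×TMB composite
  group; independent exponential censoring, optional follow-up cap.
* **Variants** — per-sample burden classes drawn independently of
  inflammation; kept SNV counts are planted so that the post-filter TMB
  lands in the class's range, plus decoy variants (low VAF, failed quality,
  common SNPs) that the somatic filter must remove and a small indel
  fraction excluded from the numerator.

What passing tests on these cohorts shows: the pipeline recovers structure
of exactly the kind it assumes (one latent immune axis, step hazards,
planted classes) at realistic sizes and noise levels. What it does not
show: robustness to real inter-gene correlation beyond one factor, batch
effects, assay chemistry artifacts, or annotation errors in variant tables.

Problem sizes used by the test-suite and the acceptance script (chosen to
make the estimates stable at desk scale): full profiling cohort 688
(QC rate), cluster recovery n = 60 with 250 resamples, differential
expression 30 + 30, cutpoint recovery 100 cohorts of n = 120, null
calibrations 120–200 cohorts of n = 12–60 with 60 bootstrap draws each,
burden cohort n = 73, composite-survival cohort n = 600. Estimated 3-year
OS in the measured extreme composite groups is pulled 2–3 points toward
the middle by score misclassification at the TIS = 9 boundary (hazards
follow the latent score, measurement uses the realized one); this is an
expected attenuation, not a defect.

## Numerical conventions

* Geometric means floor their inputs (default 1; `1e-12` in algebraic
  identity tests where exactness matters more than count semantics).
* Hierarchical merges use scipy's deterministic linkage; consensus runs are
  bitwise reproducible given a seed.
* Cutpoint ties break toward the smallest cutoff.
* RCC section tags are matched case-insensitively; quoted and unquoted CSV
  fields are both accepted. Gene symbol matching everywhere is exact and
  case-sensitive (closed panel vocabulary, no alias resolution).

## Known limitations

* Normalization levels are batch-relative (see above); cross-batch score
  comparisons require shared reference samples.
* The GSVA τ and kernel options are fixed to the conventional defaults.
* The bootstrap cutpoint p summarizes by the median of selection-adjusted
  replicate p-values; other published pipelines summarize differently, so
  absolute p-values are comparable only under the same convention.
* No lane-level binding-density QC, no background subtraction, no
  batch-effect correction, no competing risks or time-varying covariates.
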