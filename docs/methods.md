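# Methods

## Model and procedure

The package tests, per variant–gene pair, two distinct hypotheses about
how a biallelic genotype (coded as minor-allele count g ∈ {0,1,2})
relates to a gene's expression in one tissue:

* **Variance (veQTL).** Equality of expression variance across genotype
  groups, tested with the Brown–Forsythe statistic: observations are
  transformed to absolute deviations from their group median,
  Z_ij = |y_ij − median_i|, and a one-way ANOVA F-ratio W is formed on
  the Z values. Under the null W ~ F(k−1, N−k) with k groups and N
  subjects. Median (rather than mean) centering keeps the type-I error
  close to nominal for non-normal expression distributions.
* **Mean (eQTL).** An additive dosage effect, tested by OLS of residual
  expression on g with a two-sided t-test on the slope (N−2 df).

Both scans run on the *same* covariate-corrected residual matrix.
Residualization regresses each gene on intercept + age + sex once per
tissue; running the dosage regression on those residuals is equivalent
to including the covariates in the eQTL model whenever genotype is
uncorrelated with them in expectation, which holds by construction in
the simulations and approximately in donor cohorts. The assumptions are
therefore: expression linear in age/sex with genotype-independent
covariate effects; independent subjects; and, for the exactness of the F
calibration, roughly symmetric unimodal residuals (the test is robust
beyond that).

Preprocessing mirrors standard tissue-expression QTL practice:
genotypes are kept only when at least two genotype classes each contain
at least `min_group` subjects (a variant whose second class is smaller
can never be tested, because the scan drops classes below `min_group`
and needs two); genes are kept when expression exceeds 0.1 (RPKM-like
units, strict inequality) in at least 10 samples; subjects with several
samples are collapsed by the arithmetic mean before residualization;
and after intersecting genotype and expression subjects the genotype
class-size rule is re-checked, since the intersection can shrink a
class below the testable floor. Missing genotype calls are excluded
pairwise (the subject is dropped only for that variant); no imputation,
no hidden-factor correction, no normalization beyond the above.

## Post-scan interpretation

* **Significance** is a fixed genome-wide threshold, strict
  p < 5 × 10⁻⁸, with no multiple-testing correction; a
  Benjamini–Hochberg helper exists for users who prefer FDR control.
  Degenerate statistics (0/0 deviations, perfect fits) are never called
  significant.
* **cis/trans**: cis iff same chromosome and |variant position − gene
  TSS| ≤ 1 Mb, boundary inclusive. The TSS was chosen as the gene anchor
  (over midpoint or nearest edge) because it is the reference point
  annotation files reliably provide; the window is configurable.
* **Dispersion classes** operationalize the qualitative Class I/II/III
  patterns with a relative tolerance τ = 0.25 on the per-group mean
  absolute deviations D_g: two dispersions agree when
  |a − b| ≤ τ·max(a,b) and differ when the gap exceeds that. Class II
  requires strict monotonicity in dosage with both steps differing;
  Class I requires D₂ to differ from D₀ while D₀ and D₁ agree; Class III
  requires D₁ to differ from both homozygote groups, which agree. Rules
  are checked in the order II, I, III; two-group tests are
  `unclassified` (no minor-homozygote group to judge). τ is exposed in
  the configuration; 0.25 separates planted multipliers ≥ 2 reliably
  while absorbing sampling noise in group MADs at n ≥ 300.
* **Genomic inflation** uses the median-based estimator
  λ = median(χ²₁-quantile of 1 − p) / 0.4549. Zero p-values are clamped
  to the smallest positive double with a warning. Q–q expected values
  use plotting positions (i − 0.5)/n on the −log₁₀ scale, under which
  the deterministic grid gives λ = 1 to interpolation error.
* **Candidate genes** must pass three criteria: significant veQTL in the
  focal tissue, significant in no other supplied tissue, and not a
  significant eQTL for the same pair in the focal tissue. Both filters
  are pure set operations (idempotent, order-independent, monotone in
  the non-focal tissue list).
* **Enrichment** is the one-sided hypergeometric upper tail
  P(X ≥ x) for the candidate/gene-set overlap within the background
  universe, BH-adjusted across sets. The background is the tissue's
  post-filter transcriptome, not the whole genome — using the genome
  would overstate enrichment of ubiquitously expressed pathways.

## Synthetic data

The generator emulates the cohort structure the scans assume: genotypes
are Binomial(2, MAF) draws (Hardy–Weinberg; no linkage disequilibrium or
population structure), age is uniform on [20, 70] years, sex is an
exactly balanced binary covariate, and a configurable fraction of
subjects (default 15%) contributes two samples with independent noise.
Expression is Gaussian around
base_mean + β·g + age_slope·age + sex_offset·sex with sd = base_sd
times a genotype-dependent multiplier: Class I multiplies the sd of the
g = 2 group only, Class II scales it geometrically (sd·m^g), Class III
multiplies the g = 1 group only. The matrix is shifted by a single
constant (recorded in the fixture manifest) so values are non-negative;
a constant shift, unlike truncation, leaves the planted variance
structure intact and is absorbed by the regression intercept.

Defaults (n_subjects = 300, MAF = 0.3, base 5 ± 1, age slope
0.02 units/year, sex offset 0.5) model a mid-sized normal-tissue cohort.
Gaussian noise was chosen because it makes the F calibration exact for
oracle tests; a realistic RNA-seq count model (negative binomial,
mean–variance coupling) is deliberately out of scope, so passing tests
demonstrate correctness of the statistics and plumbing, not robustness
to count-data skew. Determinism: one master seed fans out into
per-variant, per-gene, covariate and design substreams
(`SeedSequence(seed, spawn_key=...)`), so identical specs reproduce
files byte-for-byte and adding genes or variants never perturbs earlier
columns.

## Numerical choices

* p-values come from survival functions (`f.sf`, `t.sf`) rather than
  1 − CDF, keeping values near 5 × 10⁻⁸ accurate.
* Group medians use the midpoint convention for even sizes (numpy
  default).
* Degenerate Brown–Forsythe inputs: all deviations zero in every group
  is a 0/0 flagged with p undefined; zero within-group scatter with
  nonzero between-group scatter reports W = ∞, p = 0, flagged; equal
  constant deviations across groups is a zero numerator, W = 0, p = 1.
* A perfect eQTL fit (zero residual sum of squares relative to 1e-12 of
  the response scale) reports p = 0 with a flag instead of dividing by
  zero.
* Residualization uses a single `numpy.linalg.lstsq` across all genes;
  constant covariate columns (e.g. single-sex tissues) are dropped with
  a warning rather than failing.
* The dosage regression uses all subjects with a genotype call,
  including classes too small for the variance test (additive coding
  does not need per-class floors).

## Validation design and problem sizes

The validation utilities (`veqtl.evaluation`) measure: agreement with
scipy's independent median-centered Levene implementation on 1,000
random grouped datasets (k ∈ {2,3}, sizes 2–30); null type-I error and
KS uniformity on 10,000 single-variant tests at n = 300, MAF 0.3 with
replicate_rate 0 (a pure Gaussian null — replicate averaging would mix
two noise scales within groups and blur the calibration being measured);
power and label accuracy for 200 planted replicates per class at
multiplier 3, n = 500, spread over 10 independent genotype draws; and a
mean-effect control (β = 1) verifying the variance scan ignores pure
location shifts. These sizes run in seconds on one core because both
scans are vectorized across genes.

## Known limitations

* No LD between variants, no population stratification, no count-based
  noise model in the generator; real-data robustness to those features
  is untested here.
* The dispersion-class rule is a deterministic operationalization of
  patterns that are descriptive in practice; borderline dispersion
  profiles land in `unclassified` by design.
* Whether expression should be log-transformed before residualization
  is data-dependent; a `log2_offset` option exists and is off by
  default.
* Only age and sex are corrected; expression heterogeneity from unknown
  technical factors propagates into both scans.
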