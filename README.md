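# veqtl

Variance-QTL (veQTL) and eQTL mapping for genotype–expression data, built
around the Brown–Forsythe test of equal variances.

## The problem

Most regulatory-variant analyses ask whether a genotype shifts the *mean*
expression of a gene (eQTL mapping). But genotypes can also govern how
*variable* a gene's expression is across individuals, and variants that
change expression variance — variable-expression QTL, or veQTL — can point
to candidate disease genes that mean-based scans miss entirely. This
package maps both kinds of association for a panel of variants (for
example, GWAS risk variants) against a tissue's transcriptome, compares
and contrasts the two scans, and distills tissue-specific candidate genes
for downstream pathway analysis.

Because the cohorts this analysis is designed for (donor genotypes plus
per-tissue RNA-seq, e.g. GTEx) are access-restricted, the package ships a
first-class synthetic-data generator that emulates the assumed data
structure — Hardy–Weinberg genotypes, covariate effects, replicate
samples, and planted mean- and variance-effects — so the whole pipeline
is testable end to end without restricted data.

## The statistic

Genotypes are coded as minor-allele counts g ∈ {0, 1, 2}. For one
variant–gene pair, let y_ij be the covariate-corrected residual
expression of subject j in genotype group i. Each observation is
transformed to its absolute deviation from the group median,
Z_ij = |y_ij − median_i|, and the Brown–Forsythe statistic is the
one-way ANOVA F-ratio on the Z values:

    W = (N − k) Σ_i N_i (Z̄_i − Z̄_··)² / [ (k − 1) Σ_i Σ_j (Z_ij − Z̄_i)² ]

with k genotype groups (2 or 3), group sizes N_i, N = Σ N_i, and Z̄_··
the grand mean of all deviations. Under the null of equal group
variances, W ~ F(k − 1, N − k); the upper tail gives the p-value. Median
centering makes the test robust to non-normal expression distributions.
Genotype classes with fewer than 10 subjects are excluded from the test
(a two-group test is run when only two classes are large enough).

The companion eQTL scan regresses the same residuals on allele dosage
(slope = S_xy/S_xx, two-sided t-test on N − 2 df).

Significant veQTL (p < 5 × 10⁻⁸) are labelled cis/trans (±1 Mb around
the gene TSS), assigned a dispersion class from the per-group mean
absolute deviations — Class I (minor-homozygote-specific,
recessive-like), Class II (dosage-dependent), Class III
(heterozygote-specific) — filtered for tissue specificity, cross-filtered
against eQTL hits, and passed to a hypergeometric gene-set
over-representation test against the tissue's background transcriptome.

## Worked example

```python
from veqtl import SimulationSpec, EffectSpec, simulate_dataset, QTLScan

spec = SimulationSpec(
    n_subjects=400, n_variants=5, n_genes=20, maf=0.3, seed=2024,
    planted_effects=[
        EffectSpec(0, 0, "var_class_I", var_multiplier=4.0),   # variance effect
        EffectSpec(3, 3, "mean_additive", mean_beta=1.5),      # mean effect
    ],
)
ds = simulate_dataset(spec)
model = QTLScan(ds.genotypes, ds.expression, covariates=ds.covariates,
                tissue="breast")
res = model.fit().call_significant().annotate_cis_trans().classify()
print(res.summary())
```

which prints

```
tissue  test  n_pairs  n_significant  n_variants  n_genes   lambda  n_cis
breast veQTL      100              1           1        1 0.914048      1
breast  eQTL      100              1           1        1 0.992175      1
```

Both scans tested all 5 × 20 = 100 variant–gene pairs. The planted
variance effect is the single significant veQTL and the planted mean
shift is the single significant eQTL — each scan finds its own effect
and not the other's. The genomic inflation factors (λ, the observed
median association chi-square over its null expectation) sit near 1,
showing neither scan is systematically inflated on the 98 null pairs.
The significant records themselves:

```
variant_id  gene_id  test  statistic            p cis_trans    class_label
   var0000 gene0000 veQTL  93.796740 4.359164e-34       cis              I
   var0003 gene0003  eQTL  19.944052 7.443100e-62       cis not_applicable
```

The veQTL hit is correctly assigned dispersion Class I — only the
minor-allele homozygotes have their expression spread multiplied.

The same analysis runs from the shell over multi-tissue configurations:

```bash
veqtl simulate --spec spec.yaml --out fixture/
veqtl run --config pipeline.yaml      # preprocess -> scans -> candidates -> enrichment
```

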