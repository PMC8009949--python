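"""Synthetic genotype/expression datasets with planted variance effects.

The generator emulates the statistical design the scans assume: biallelic
genotypes drawn under Hardy-Weinberg equilibrium at a configurable minor
allele frequency, expression built from a Gaussian base with additive
mean effects, age and sex covariate effects, genotype-dependent variance
effects of three classes, and a fraction of subjects contributing two
tissue samples.

Variance effect classes mirror the dispersion patterns seen across
genotype groups in real variance-QTL hits:

* ``var_class_I``   - recessive-like: only the minor-allele homozygote
  group (dosage 2) has its residual standard deviation multiplied.
* ``var_class_II``  - dosage-dependent: the standard deviation scales
  geometrically with minor-allele count, sd * m**g.
* ``var_class_III`` - heterozygote-specific: only dosage-1 carriers have
  their standard deviation multiplied.

Determinism: a single master seed is fanned out into independent
substreams per variant, per gene, and for the covariate/replication
draws, so the same spec + seed reproduces the dataset bit for bit and
adding genes or variants never perturbs earlier columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import CovariateTable, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "EffectSpec",
    "SimulationSpec",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
    "write_fixture",
]

EFFECT_KINDS = ("mean_additive", "var_class_I", "var_class_II", "var_class_III")

# substream namespaces under the master seed
_NS_VARIANT, _NS_GENE, _NS_COVARIATE, _NS_DESIGN = 0, 1, 2, 3


@dataclass(frozen=True)
class EffectSpec:
    """One planted variant -> gene effect.

    ``mean_beta`` (expression units per allele copy) applies only to
    ``mean_additive``; ``var_multiplier`` (dimensionless, >= 1) applies to
    the variance classes and multiplies the residual standard deviation
    of the affected genotype group(s).
    """

    variant_index: int
    gene_index: int
    kind: str
    mean_beta: float = 0.0
    var_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}; one of {EFFECT_KINDS}")
        if self.var_multiplier < 1.0:
            raise ValueError("var_multiplier must be >= 1")

    @property
    def is_null(self) -> bool:
        if self.kind == "mean_additive":
            return self.mean_beta == 0.0
        return self.var_multiplier == 1.0


@dataclass
class SimulationSpec:
    """Full description of a synthetic dataset.

    Defaults model a mid-sized normal-tissue expression cohort: a few
    hundred donors, MAF 0.3 variants, base expression 5 +/- 1 (RPKM-like
    units after the non-negativity shift), a mild age trend, a balanced
    binary sex covariate, and ~15% of donors contributing two samples.
    """

    n_subjects: int = 300
    n_variants: int = 10
    n_genes: int = 50
    maf: float | list = 0.3
    planted_effects: list = field(default_factory=list)
    base_mean: float = 5.0
    base_sd: float = 1.0
    age_slope: float = 0.02
    sex_offset: float = 0.5
    replicate_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_variants, self.n_genes) < 1:
            raise ValueError("n_subjects, n_variants and n_genes must be >= 1")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be > 0")
        if not 0.0 <= self.replicate_rate <= 1.0:
            raise ValueError("replicate_rate must be in [0, 1]")
        for i, f in enumerate(self.maf_per_variant):
            if not 0.0 < f <= 0.5:
                raise ValueError(f"variant {i}: MAF must be in (0, 0.5], got {f}")
        effects = []
        for e in self.planted_effects:
            if isinstance(e, dict):
                e = EffectSpec(**e)
            effects.append(e)
        self.planted_effects = effects
        for e in effects:
            if not 0 <= e.variant_index < self.n_variants:
                raise ValueError(f"effect references missing variant {e.variant_index}")
            if not 0 <= e.gene_index < self.n_genes:
                raise ValueError(f"effect references missing gene {e.gene_index}")

    @property
    def maf_per_variant(self) -> np.ndarray:
        if np.isscalar(self.maf):
            return np.full(self.n_variants, float(self.maf))
        arr = np.asarray(self.maf, dtype=float)
        if arr.size != self.n_variants:
            raise ValueError("maf list length must equal n_variants")
        return arr

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_subjects", "n_variants", "n_genes", "base_mean", "base_sd",
                "age_slope", "sex_offset", "replicate_rate", "seed",
            )
        }
        maf = self.maf_per_variant
        d["maf"] = float(maf[0]) if np.all(maf == maf[0]) else [float(x) for x in maf]
        d["planted_effects"] = [
            {
                "variant_index": e.variant_index,
                "gene_index": e.gene_index,
                "kind": e.kind,
                "mean_beta": e.mean_beta,
                "var_multiplier": e.var_multiplier,
            }
            for e in self.planted_effects
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        return cls(**d)


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    covariates: CovariateTable
    spec: SimulationSpec
    offset: float  # constant added to keep expression non-negative


def _rng(seed: int, namespace: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(namespace, index))
    )


def _variant_ids(n: int) -> list:
    return [f"var{i:04d}" for i in range(n)]


def _gene_ids(n: int) -> list:
    return [f"gene{i:04d}" for i in range(n)]


def _subject_ids(n: int) -> list:
    return [f"subj{i:04d}" for i in range(n)]


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw minor-allele counts under Hardy-Weinberg at each variant's MAF.

    Each genotype is Binomial(2, maf), i.e. frequencies (1-f)^2, 2f(1-f),
    f^2 for 0/1/2 minor alleles.  Each variant uses its own seed
    substream, so genotype columns do not change when more variants or
    genes are added to the spec.
    """
    mafs = spec.maf_per_variant
    cols = {}
    for i, vid in enumerate(_variant_ids(spec.n_variants)):
        rng = _rng(spec.seed, _NS_VARIANT, i)
        cols[vid] = rng.binomial(2, mafs[i], size=spec.n_subjects).astype(float)
    calls = pd.DataFrame(cols, index=_subject_ids(spec.n_subjects))
    meta = pd.DataFrame(
        {
            "chrom": [f"chr{1 + i % 22}" for i in range(spec.n_variants)],
            "pos": [1_000_000 + 10_000 * i for i in range(spec.n_variants)],
            "ref": "A",
            "alt": "G",
        },
        index=calls.columns,
    )
    return GenotypeMatrix(calls, meta)


def simulate_covariates(spec: SimulationSpec) -> CovariateTable:
    """Age uniform on [20, 70]; sex exactly balanced and randomly assigned."""
    rng = _rng(spec.seed, _NS_COVARIATE)
    n = spec.n_subjects
    age = rng.uniform(20.0, 70.0, size=n)
    sex = np.zeros(n, dtype=int)
    sex[: n // 2] = 1
    sex = rng.permutation(sex)
    tbl = pd.DataFrame({"age": age, "sex": sex}, index=_subject_ids(n))
    return CovariateTable(tbl)


def _replicated_subjects(spec: SimulationSpec) -> np.ndarray:
    rng = _rng(spec.seed, _NS_DESIGN)
    n_rep = int(round(spec.replicate_rate * spec.n_subjects))
    return np.sort(rng.choice(spec.n_subjects, size=n_rep, replace=False))


def _sd_multiplier(kind: str, m: float, g: np.ndarray) -> np.ndarray:
    if kind == "var_class_I":
        return np.where(g == 2, m, 1.0)
    if kind == "var_class_II":
        return m**g
    if kind == "var_class_III":
        return np.where(g == 1, m, 1.0)
    raise ValueError(kind)


def simulate_expression(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, float]:
    """Build the genes x samples expression matrix from the planted model.

    Per subject s and gene j:

        y = base_mean + sum(beta * g_s) + age_slope*age_s + sex_offset*sex_s
            + eps,   eps ~ N(0, (base_sd * prod(multipliers))^2)

    Replicated subjects contribute two samples with independent noise.
    The whole matrix is then shifted by a single constant so its minimum
    is zero whenever any value is negative (expression-like
    non-negativity without truncating the planted variance structure).

    Returns the matrix and the shift that was applied.
    """
    n_sub, n_genes = spec.n_subjects, spec.n_genes
    calls = genotypes.calls.to_numpy()
    cov = covariates.table.loc[genotypes.subject_ids]
    age = cov["age"].to_numpy()
    sex = cov["sex"].to_numpy(dtype=float)

    mean = np.full((n_genes, n_sub), spec.base_mean)
    mean += spec.age_slope * age + spec.sex_offset * sex
    sd = np.full((n_genes, n_sub), spec.base_sd)
    for e in spec.planted_effects:
        g = calls[:, e.variant_index]
        if e.kind == "mean_additive":
            mean[e.gene_index] += e.mean_beta * g
        else:
            sd[e.gene_index] *= _sd_multiplier(e.kind, e.var_multiplier, g)

    rep = _replicated_subjects(spec)
    rep_set = set(rep.tolist())
    sample_subject_idx: list[int] = []
    sample_ids: list[str] = []
    for i, sid in enumerate(genotypes.subject_ids):
        sample_subject_idx.append(i)
        sample_ids.append(f"{sid}-s1")
        if i in rep_set:
            sample_subject_idx.append(i)
            sample_ids.append(f"{sid}-s2")
    sub_idx = np.asarray(sample_subject_idx)
    n_samples = len(sample_ids)

    values = np.empty((n_genes, n_samples))
    for j in range(n_genes):
        rng = _rng(spec.seed, _NS_GENE, j)
        eps = rng.standard_normal(n_samples) * sd[j, sub_idx]
        values[j] = mean[j, sub_idx] + eps

    low = values.min()
    offset = float(-low) if low < 0 else 0.0
    values += offset

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=_gene_ids(n_genes), columns=sample_ids),
        pd.Series(
            [genotypes.subject_ids[i] for i in sub_idx], index=sample_ids, name="subject_id"
        ),
        gene_meta=pd.DataFrame(
            {
                "chrom": [f"chr{1 + j % 22}" for j in range(n_genes)],
                "tss": [500_000 + 50_000 * j for j in range(n_genes)],
                "strand": ["+" if j % 2 == 0 else "-" for j in range(n_genes)],
            },
            index=_gene_ids(n_genes),
        ),
    )
    return expr, offset


def simulate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Generate the full genotype/expression/covariate bundle for a spec."""
    genotypes = simulate_genotypes(spec)
    covariates = simulate_covariates(spec)
    expression, offset = simulate_expression(genotypes, covariates, spec)
    return SyntheticDataset(genotypes, expression, covariates, spec, offset)


_FLOAT_FMT = "%.10g"


def write_fixture(dataset: SyntheticDataset, directory) -> dict:
    """Write a dataset as a plain-text fixture directory.

    Emits a genotype TSV (subjects x variants) and an equivalent minimal
    VCF 4.2 (GT only), expression as GCT 1.2 and plain TSV, a
    sample-to-subject map, covariates, variant and gene annotation TSVs,
    and a YAML manifest echoing the spec (plus the applied non-negativity
    offset) so the dataset can be regenerated byte-identically.

    Returns a dict of the written paths.
    """
    from . import io as vio  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_tsv": directory / "genotypes.tsv",
        "genotypes_vcf": directory / "genotypes.vcf",
        "expression_gct": directory / "expression.gct",
        "expression_tsv": directory / "expression.tsv",
        "samples_tsv": directory / "samples.tsv",
        "covariates_tsv": directory / "covariates.tsv",
        "variants_tsv": directory / "variants.tsv",
        "genes_tsv": directory / "genes.tsv",
        "manifest": directory / "manifest.yaml",
    }
    vio.write_genotype_tsv(dataset.genotypes, paths["genotypes_tsv"])
    vio.write_vcf(dataset.genotypes, paths["genotypes_vcf"])
    vio.write_gct(dataset.expression, paths["expression_gct"])
    vio.write_expression_tsv(dataset.expression, paths["expression_tsv"])
    vio.write_sample_map(dataset.expression, paths["samples_tsv"])
    vio.write_covariates_tsv(dataset.covariates, paths["covariates_tsv"])
    vio.write_variant_annotation(dataset.genotypes.variant_meta, paths["variants_tsv"])
    vio.write_gene_annotation(dataset.expression.gene_meta, paths["genes_tsv"])
    manifest = {
        "format": "veqtl-fixture-v1",
        "spec": dataset.spec.to_dict(),
        "offset": dataset.offset,
        "n_samples": int(dataset.expression.values.shape[1]),
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
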