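"""File formats and preprocessing for QTL mapping.

Readers/writers for the plain-text interchange formats (genotype dosage
TSV, minimal VCF 4.2, GCT 1.2, covariate/annotation TSVs, GMT gene sets)
plus the preprocessing chain applied before any scan:

1. ``filter_genotypes``  - keep biallelic variants with at least two
   genotype classes of >= ``min_group`` subjects each,
2. ``filter_expression`` - keep genes expressed above a floor in enough
   samples,
3. ``collapse_replicates`` - average the samples of each subject,
4. ``residualize``       - per-gene OLS on intercept + age + sex,
5. ``align``             - intersect genotype and expression subjects and
   re-check the genotype group-size rule.

All coordinates are 1-based as in VCF.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    ResidualExpressionMatrix,
)

log = logging.getLogger("veqtl")

__all__ = [
    "read_genotype_tsv", "write_genotype_tsv",
    "read_vcf", "write_vcf",
    "read_gct", "write_gct",
    "read_expression_tsv", "write_expression_tsv",
    "read_sample_map", "write_sample_map",
    "read_covariates_tsv", "write_covariates_tsv",
    "read_variant_annotation", "write_variant_annotation",
    "read_gene_annotation", "write_gene_annotation",
    "read_gmt",
    "read_fixture",
    "filter_genotypes", "filter_expression",
    "collapse_replicates", "residualize", "align",
]

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# genotype formats

def read_genotype_tsv(path, annotation=None) -> GenotypeMatrix:
    """Read a subjects x variants minor-allele-count matrix.

    First column = subject id, header row = variant ids, empty/NA cells =
    missing calls.  ``annotation`` optionally supplies a variant metadata
    table (see :func:`read_variant_annotation`).
    """
    calls = pd.read_csv(path, sep="\t", index_col=0)
    calls.index = calls.index.astype(str)
    meta = read_variant_annotation(annotation) if annotation is not None else None
    return GenotypeMatrix(calls.astype(float), meta)


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    out = g.calls.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", float_format="%g", na_rep="NA")


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write calls as a minimal VCF 4.2 with only the GT field.

    The ALT allele is taken to be the minor allele, so the written GT
    codes equal the minor-allele counts.  Requires variant metadata with
    chrom/pos (ref/alt default to A/G).
    """
    if g.variant_meta is None:
        raise ValueError("variant metadata (chrom, pos) required to write VCF")
    meta = g.variant_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.subject_ids))
            + "\n"
        )
        calls = g.calls.to_numpy()
        for j, vid in enumerate(g.variant_ids):
            row = meta.loc[vid]
            ref = row.get("ref", "A") if hasattr(row, "get") else "A"
            alt = row.get("alt", "G") if hasattr(row, "get") else "G"
            gts = [
                "./." if np.isnan(c) else _GT_CODE[c] for c in calls[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into minor-allele-count coding.

    Multiallelic records and half-calls are rejected at parse time with
    the counts logged; ALT counts are flipped to minor-allele counts when
    the ALT frequency exceeds 0.5.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols, ids, meta_rows = [], [], []
    n_multi = n_half = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotypes  # [a0, a1, phased]
        col = np.empty(len(subjects))
        half = False
        for i, (a0, a1, *_rest) in enumerate(gts):
            if a0 < 0 and a1 < 0:
                col[i] = np.nan
            elif a0 < 0 or a1 < 0:
                half = True
                break
            else:
                col[i] = a0 + a1
        if half:
            n_half += 1
            continue
        finite = col[~np.isnan(col)]
        if finite.size and finite.mean() > 1.0:  # ALT is the major allele: flip
            col = 2.0 - col
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        ids.append(vid)
        cols.append(col)
        meta_rows.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if n_multi or n_half:
        log.warning("read_vcf: rejected %d multiallelic and %d half-call records",
                    n_multi, n_half)
    calls = pd.DataFrame(np.column_stack(cols), index=subjects, columns=ids)
    meta = pd.DataFrame(
        meta_rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    ).set_index("variant_id")
    return GenotypeMatrix(calls, meta)


# ---------------------------------------------------------------------------
# expression formats

def write_gct(e: ExpressionMatrix, path) -> None:
    """Write expression in GCT 1.2 (Name/Description + sample columns)."""
    n_genes, n_samples = e.values.shape
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_genes}\t{n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, e.sample_ids)) + "\n")
        vals = e.values.to_numpy()
        for i, gid in enumerate(e.gene_ids):
            fh.write(
                f"{gid}\t{gid}\t" + "\t".join(_FLOAT_FMT % v for v in vals[i]) + "\n"
            )


def read_gct(path, sample_map, gene_annotation=None) -> ExpressionMatrix:
    """Read a GCT 1.2 file; ``sample_map`` supplies sample -> subject."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2",):
            raise ValueError(f"unsupported GCT version line {version!r}")
        n_genes, n_samples = map(int, fh.readline().split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"GCT header declares {n_genes}x{n_samples} but body is {df.shape}"
        )
    s2s = read_sample_map(sample_map) if not isinstance(sample_map, pd.Series) else sample_map
    meta = read_gene_annotation(gene_annotation) if gene_annotation is not None else None
    return ExpressionMatrix(df.astype(float), s2s, meta)


def write_expression_tsv(e: ExpressionMatrix, path) -> None:
    out = e.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression_tsv(path, sample_map, gene_annotation=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s2s = read_sample_map(sample_map) if not isinstance(sample_map, pd.Series) else sample_map
    meta = read_gene_annotation(gene_annotation) if gene_annotation is not None else None
    return ExpressionMatrix(df.astype(float), s2s, meta)


def write_sample_map(e: ExpressionMatrix, path) -> None:
    df = e.sample_to_subject.rename("subject_id").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_sample_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "subject_id"):
        if col not in df.columns:
            raise ValueError(f"sample map missing required column {col!r}")
    return df.set_index("sample_id")["subject_id"]


# ---------------------------------------------------------------------------
# covariates, annotations, gene sets

def write_covariates_tsv(cov: CovariateTable, path) -> None:
    out = cov.table.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_covariates_tsv(path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    df.index = df.index.astype(str)
    return CovariateTable(df)


def write_variant_annotation(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "variant_id"
    out.to_csv(path, sep="\t")


def read_variant_annotation(path) -> pd.DataFrame:
    if isinstance(path, pd.DataFrame):
        return path
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"variant annotation missing required column {col!r}")
    return df


def write_gene_annotation(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gene_annotation(path) -> pd.DataFrame:
    if isinstance(path, pd.DataFrame):
        return path
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("chrom", "tss"):
        if col not in df.columns:
            raise ValueError(f"gene annotation missing required column {col!r}")
    return df


def read_gmt(path) -> dict:
    """Read gene sets from GMT: set_id <tab> description <tab> members..."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            set_id, desc, members = parts[0], parts[1], parts[2:]
            members = list(dict.fromkeys(m for m in members if m))
            sets[set_id] = {"description": desc, "genes": members}
    if not sets:
        raise ValueError("GMT file contains no gene sets")
    return sets


def read_fixture(directory):
    """Read a fixture directory written by :func:`veqtl.simulate.write_fixture`.

    Returns ``(genotypes, expression, covariates, manifest)``.
    """
    directory = Path(directory)
    genotypes = read_genotype_tsv(
        directory / "genotypes.tsv", directory / "variants.tsv"
    )
    expression = read_expression_tsv(
        directory / "expression.tsv",
        directory / "samples.tsv",
        directory / "genes.tsv",
    )
    covariates = read_covariates_tsv(directory / "covariates.tsv")
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return genotypes, expression, covariates, manifest


# ---------------------------------------------------------------------------
# preprocessing

def genotype_class_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-variant counts of subjects in each genotype class (0/1/2)."""
    counts = pd.DataFrame(
        {g: (calls == g).sum(axis=0) for g in (0, 1, 2)}, index=calls.columns
    )
    return counts


def filter_genotypes(g: GenotypeMatrix, min_group: int = 10) -> GenotypeMatrix:
    """Keep variants with >= 2 genotype classes each holding >= min_group subjects.

    This is the pre-scan frequency filter: a variant whose second-largest
    genotype class is below ``min_group`` can never be tested, since the
    scan only compares classes of at least ``min_group`` subjects.
    Variant order is preserved; an empty result is allowed (with a
    warning), not an error.
    """
    if min_group < 2:
        raise ValueError("min_group must be >= 2")
    counts = genotype_class_counts(g.calls)
    keep = (counts >= min_group).sum(axis=1) >= 2
    kept = g.calls.columns[keep]
    log.info("filter_genotypes: %d -> %d variants (min_group=%d)",
             g.n_variants, len(kept), min_group)
    if len(kept) == 0:
        log.warning("filter_genotypes: no variants pass the filter")
    return g.select_variants(kept)


def filter_expression(
    e: ExpressionMatrix, min_value: float = 0.1, min_samples: int = 10
) -> ExpressionMatrix:
    """Keep genes with expression strictly above ``min_value`` in >= ``min_samples`` samples."""
    n_above = (e.values > min_value).sum(axis=1)
    kept = e.values.index[n_above >= min_samples]
    log.info("filter_expression: %d -> %d genes (> %g in >= %d samples)",
             e.n_genes, len(kept), min_value, min_samples)
    return e.select_genes(kept)


def collapse_replicates(e: ExpressionMatrix) -> ExpressionMatrix:
    """Average each subject's samples, yielding one column per subject.

    Subject column order follows first appearance in the sample list;
    single-sample subjects pass through unchanged.
    """
    subj = e.sample_to_subject
    collapsed = e.values.T.groupby(subj, sort=False).mean().T
    identity = pd.Series(collapsed.columns, index=collapsed.columns, name="subject_id")
    return ExpressionMatrix(collapsed, identity, e.gene_meta)


def residualize(
    e: ExpressionMatrix, cov: CovariateTable, log2_offset: float | None = None
) -> ResidualExpressionMatrix:
    """Regress out intercept + age + sex per gene, returning residuals.

    Expression must already be collapsed to one column per subject.
    Degenerate covariate columns (zero variance, e.g. a single-sex
    tissue) are dropped with a logged warning instead of failing.  With
    ``log2_offset`` set, log2(x + offset) is applied before the fit.
    """
    subjects = e.values.columns
    covtab = cov.loc(subjects)
    y = e.values.to_numpy(dtype=float)
    if log2_offset is not None:
        y = np.log2(y + log2_offset)

    cols = [np.ones(len(subjects))]
    names = ["intercept"]
    for name in ("age", "sex"):
        v = covtab[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            log.warning("residualize: covariate %r is constant; dropped", name)
            continue
        cols.append(v)
        names.append(name)
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y - (x @ beta).T
    return ResidualExpressionMatrix(
        pd.DataFrame(resid, index=e.values.index, columns=subjects),
        coefficients=pd.DataFrame(beta.T, index=e.values.index, columns=names),
        gene_meta=e.gene_meta,
    )


def align(
    g: GenotypeMatrix, e: ResidualExpressionMatrix, min_group: int = 10
) -> tuple[GenotypeMatrix, ResidualExpressionMatrix]:
    """Restrict both matrices to the common subjects, in the same order.

    The genotype group-size filter is re-applied after intersection,
    since dropping subjects can push a genotype class below the testable
    size.  An empty intersection is a hard error.
    """
    common = g.subject_ids.intersection(e.subject_ids, sort=False)
    if len(common) == 0:
        raise ValueError("genotype and expression matrices share no subjects")
    g2 = filter_genotypes(g.select_subjects(common), min_group=min_group)
    e2 = e.select_subjects(common)
    log.info("align: %d common subjects, %d variants, %d genes",
             len(common), g2.n_variants, len(e2.gene_ids))
    return g2, e2
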