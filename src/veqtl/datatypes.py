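"""Core in-memory containers for QTL mapping.

Genotypes are coded as minor-allele counts (0/1/2); expression is a
genes x samples matrix of non-negative RPKM-like values with an explicit
sample-to-subject mapping so that multi-sample subjects can be collapsed.
All containers are thin wrappers over pandas objects and validate their
invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "ResidualExpressionMatrix",
    "CovariateTable",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Subjects x variants matrix of minor-allele counts.

    Parameters
    ----------
    calls : DataFrame
        Rows are subjects, columns are variant ids.  Entries are 0, 1 or 2
        (number of minor alleles) or NaN for a missing call.
    variant_meta : DataFrame, optional
        Indexed by variant id with columns ``chrom``, ``pos`` (1-based) and
        optionally ``ref``/``alt``.
    """

    calls: pd.DataFrame
    variant_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "subject ids")
        _check_unique(self.calls.columns, "variant ids")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                "genotype calls must be 0/1/2 or missing; offending entry at "
                f"subject {self.calls.index[bad[0]]!r}, "
                f"variant {self.calls.columns[bad[1]]!r}"
            )
        if self.variant_meta is not None:
            missing = self.calls.columns.difference(self.variant_meta.index)
            if len(missing):
                raise ValueError(f"variants without metadata: {list(missing)[:5]}")
            self.variant_meta = self.variant_meta.loc[self.calls.columns]

    @property
    def subject_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def select_variants(self, variant_ids) -> "GenotypeMatrix":
        meta = None
        if self.variant_meta is not None:
            meta = self.variant_meta.loc[variant_ids]
        return GenotypeMatrix(self.calls.loc[:, variant_ids], meta)

    def select_subjects(self, subject_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[subject_ids], self.variant_meta)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``sample_to_subject`` maps every sample column to its donor subject;
    several samples may map to the same subject (technical/biological
    replicates) and are averaged by :func:`veqtl.io.collapse_replicates`.
    """

    values: pd.DataFrame
    sample_to_subject: pd.Series
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        unmapped = self.values.columns.difference(self.sample_to_subject.index)
        if len(unmapped):
            raise ValueError(f"samples without a subject mapping: {list(unmapped)[:5]}")
        self.sample_to_subject = self.sample_to_subject.loc[self.values.columns]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.gene_meta is not None:
            missing = self.values.index.difference(self.gene_meta.index)
            if len(missing):
                raise ValueError(f"genes without metadata: {list(missing)[:5]}")
            self.gene_meta = self.gene_meta.loc[self.values.index]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def subjects(self) -> pd.Index:
        return pd.Index(pd.unique(self.sample_to_subject.to_numpy()))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def select_genes(self, gene_ids) -> "ExpressionMatrix":
        meta = self.gene_meta.loc[gene_ids] if self.gene_meta is not None else None
        return ExpressionMatrix(self.values.loc[gene_ids], self.sample_to_subject, meta)


@dataclass
class ResidualExpressionMatrix:
    """Genes x subjects residual expression after covariate correction.

    Values are OLS residuals and may be negative.  ``coefficients`` retains
    the fitted per-gene covariate coefficients for audit output.
    """

    values: pd.DataFrame
    coefficients: pd.DataFrame | None = None
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "subject ids")
        if self.gene_meta is not None:
            missing = self.values.index.difference(self.gene_meta.index)
            if len(missing):
                raise ValueError(f"genes without metadata: {list(missing)[:5]}")
            self.gene_meta = self.gene_meta.loc[self.values.index]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.columns

    def select_subjects(self, subject_ids) -> "ResidualExpressionMatrix":
        return ResidualExpressionMatrix(
            self.values.loc[:, subject_ids], self.coefficients, self.gene_meta
        )


@dataclass
class CovariateTable:
    """Per-subject covariates: age in years and a binary sex code."""

    table: pd.DataFrame
    required: tuple = field(default=("age", "sex"), repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "subject ids")
        for col in self.required:
            if col not in self.table.columns:
                raise ValueError(f"covariate table missing required column {col!r}")
        if self.table[list(self.required)].isna().any().any():
            raise ValueError("covariate table contains missing values")

    @property
    def subject_ids(self) -> pd.Index:
        return self.table.index

    def loc(self, subject_ids) -> pd.DataFrame:
        missing = pd.Index(subject_ids).difference(self.table.index)
        if len(missing):
            raise ValueError(f"subjects without covariates: {list(missing)[:5]}")
        return self.table.loc[subject_ids]
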