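"""Variant x gene association scans and the `QTLScan` model object.

Two scans run over the same aligned genotype / residual-expression pair:

* the veQTL scan tests, per variant-gene pair, whether residual
  expression *variance* differs between genotype groups (Brown-Forsythe
  test on groups with at least ``min_group`` subjects; two-genotype
  fallback when the third class is too small);
* the eQTL scan tests the additive *mean* effect (OLS of residual
  expression on minor-allele dosage, two-sided t-test on the slope).

`QTLScan` wraps both behind a statsmodels-like interface: construct from
the data containers, call :meth:`QTLScan.fit`, and work with the returned
:class:`QTLScanResults` (tidy records, significance calls, cis/trans
annotation, dispersion-class labels, q-q / inflation diagnostics,
summary table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import postprocess as post
from .datatypes import CovariateTable, ExpressionMatrix, GenotypeMatrix, ResidualExpressionMatrix
from .io import align, collapse_replicates, residualize
from .stats import bf_matrix, ols_slope_matrix

log = logging.getLogger("veqtl")

__all__ = ["veqtl_scan", "eqtl_scan", "QTLScan", "QTLScanResults"]

RECORD_COLUMNS = [
    "variant_id", "gene_id", "test", "statistic", "df1", "df2", "p",
    "n_used", "groups_used", "mad_g0", "mad_g1", "mad_g2",
    "n_g0", "n_g1", "n_g2", "slope", "degenerate",
]


def _usable_groups(calls_col: np.ndarray, min_group: int):
    """Indices of subjects per genotype class, keeping classes >= min_group.

    Missing calls are excluded pairwise (for this variant only).  Returns
    ``(kept_classes, [index arrays])``; classes below the threshold are
    dropped, which covers the two-genotype fallback deterministically.
    """
    kept, indices = [], []
    for cls in (0, 1, 2):
        ix = np.flatnonzero(calls_col == cls)
        if ix.size >= min_group:
            kept.append(cls)
            indices.append(ix)
    return kept, indices


def veqtl_scan(
    genotypes: GenotypeMatrix,
    expression: ResidualExpressionMatrix,
    min_group: int = 10,
) -> pd.DataFrame:
    """Brown-Forsythe variance scan over every variant-gene pair.

    For each variant the genotype classes with fewer than ``min_group``
    subjects are dropped; if at least two classes remain, the test runs
    on those classes for every gene.  Output is variant-major, then gene,
    with the classes used and their per-group mean absolute deviations
    recorded for downstream classification.
    """
    if not genotypes.subject_ids.equals(expression.subject_ids):
        raise ValueError("genotypes and expression must be aligned (same subjects, same order)")
    y = expression.values.to_numpy(dtype=float)
    calls = genotypes.calls.to_numpy(dtype=float)
    genes = list(expression.gene_ids)
    frames = []
    for j, vid in enumerate(genotypes.variant_ids):
        kept, indices = _usable_groups(calls[:, j], min_group)
        if len(kept) < 2:
            log.warning("veqtl_scan: variant %s has <2 usable genotype classes; skipped", vid)
            continue
        res = bf_matrix(y, indices)
        mad = {f"mad_g{c}": np.nan for c in (0, 1, 2)}
        n_by = {f"n_g{c}": 0 for c in (0, 1, 2)}
        for pos, cls in enumerate(kept):
            mad[f"mad_g{cls}"] = res["group_mad"][:, pos]
            n_by[f"n_g{cls}"] = int(res["group_sizes"][pos])
        frames.append(pd.DataFrame({
            "variant_id": vid,
            "gene_id": genes,
            "test": "veQTL",
            "statistic": res["statistic"],
            "df1": res["df1"],
            "df2": res["df2"],
            "p": res["p"],
            "n_used": int(res["group_sizes"].sum()),
            "groups_used": ",".join(map(str, kept)),
            **mad,
            **n_by,
            "slope": np.nan,
            "degenerate": res["degenerate"],
        }))
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]


def eqtl_scan(
    genotypes: GenotypeMatrix,
    expression: ResidualExpressionMatrix,
) -> pd.DataFrame:
    """Additive-model mean-effect scan over every variant-gene pair.

    Residual expression is regressed on minor-allele dosage over all
    subjects with a genotype call; pairs whose genotype vector is
    constant after the subject drop are skipped with a log entry.  Pair
    ordering matches :func:`veqtl_scan`.
    """
    if not genotypes.subject_ids.equals(expression.subject_ids):
        raise ValueError("genotypes and expression must be aligned (same subjects, same order)")
    y_all = expression.values.to_numpy(dtype=float)
    calls = genotypes.calls.to_numpy(dtype=float)
    genes = list(expression.gene_ids)
    frames = []
    for j, vid in enumerate(genotypes.variant_ids):
        ok = ~np.isnan(calls[:, j])
        g = calls[ok, j]
        if g.size < 3 or np.ptp(g) == 0:
            log.warning("eqtl_scan: variant %s has constant/insufficient genotypes; skipped", vid)
            continue
        res = ols_slope_matrix(y_all[:, ok], g)
        frames.append(pd.DataFrame({
            "variant_id": vid,
            "gene_id": genes,
            "test": "eQTL",
            "statistic": res["t"],
            "df1": 1,
            "df2": res["n"] - 2,
            "p": res["p"],
            "n_used": res["n"],
            "groups_used": "",
            "mad_g0": np.nan, "mad_g1": np.nan, "mad_g2": np.nan,
            "n_g0": int((g == 0).sum()),
            "n_g1": int((g == 1).sum()),
            "n_g2": int((g == 2).sum()),
            "slope": res["slope"],
            "degenerate": res["perfect_fit"],
        }))
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]


@dataclass
class QTLScanResults:
    """Fitted scan results: one record per variant-gene pair per test."""

    records: pd.DataFrame
    min_group: int
    tissue: str | None = None
    variant_meta: pd.DataFrame | None = None
    gene_meta: pd.DataFrame | None = None

    def subset(self, test: str) -> pd.DataFrame:
        return self.records[self.records["test"] == test].reset_index(drop=True)

    @property
    def veqtl(self) -> pd.DataFrame:
        return self.subset("veQTL")

    @property
    def eqtl(self) -> pd.DataFrame:
        return self.subset("eQTL")

    def call_significant(self, threshold: float = 5e-8) -> "QTLScanResults":
        return self._replace(post.call_significant(self.records, threshold))

    def annotate_cis_trans(self, window: int = 1_000_000) -> "QTLScanResults":
        if self.variant_meta is None or self.gene_meta is None:
            raise ValueError("variant and gene annotation required for cis/trans labels")
        return self._replace(
            post.annotate_cis_trans(self.records, self.variant_meta, self.gene_meta, window)
        )

    def classify(self, tolerance: float = 0.25, threshold: float = 5e-8) -> "QTLScanResults":
        rec = self.records
        if "significant" not in rec.columns:
            rec = post.call_significant(rec, threshold)
        return self._replace(post.classify_records(rec, tolerance=tolerance))

    def genomic_inflation(self, test: str = "veQTL") -> post.InflationReport:
        sub = self.subset(test)
        p = sub.loc[~sub["degenerate"], "p"].dropna().to_numpy()
        return post.genomic_inflation(p, tissue=self.tissue, test=test)

    def rank_correlation(self) -> float:
        return post.rank_correlation(self.veqtl, self.eqtl)

    def summary(self, threshold: float = 5e-8) -> pd.DataFrame:
        """Per-test tally: pairs tested, significant hits, distinct
        variants/genes among hits, cis hits (when annotated), and λ."""
        rec = self.records
        if "significant" not in rec.columns:
            rec = post.call_significant(rec, threshold)
        rows = []
        for test in rec["test"].unique():
            sub = rec[rec["test"] == test]
            sig = sub[sub["significant"]]
            row = {
                "tissue": self.tissue or "-",
                "test": test,
                "n_pairs": len(sub),
                "n_significant": len(sig),
                "n_variants": sig["variant_id"].nunique(),
                "n_genes": sig["gene_id"].nunique(),
                "lambda": self.genomic_inflation(test).lam,
            }
            if "cis_trans" in sig.columns:
                row["n_cis"] = int((sig["cis_trans"] == "cis").sum())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def _replace(self, records: pd.DataFrame) -> "QTLScanResults":
        return QTLScanResults(records, self.min_group, self.tissue,
                              self.variant_meta, self.gene_meta)


@dataclass
class QTLScan:
    """Joint veQTL/eQTL scan model over an aligned genotype-expression pair.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Minor-allele-count calls (pre-filtered or not; the group-size
        rule is re-checked during alignment).
    expression : ResidualExpressionMatrix or ExpressionMatrix
        Covariate-corrected residuals per subject.  A raw
        ``ExpressionMatrix`` plus ``covariates`` may be given instead, in
        which case replicate collapsing and residualization run here.
    covariates : CovariateTable, optional
    min_group : int
        Minimum genotype-class size entering the variance test.
    tissue : str, optional
        Label carried into the results for multi-tissue workflows.

    Examples
    --------
    >>> model = QTLScan(genotypes, expression, covariates=covs, tissue="breast")
    >>> results = model.fit()
    >>> results.summary()
    """

    genotypes: GenotypeMatrix
    expression: ResidualExpressionMatrix | ExpressionMatrix
    covariates: CovariateTable | None = None
    min_group: int = 10
    tissue: str | None = None
    _aligned: tuple = field(default=None, repr=False)

    def __post_init__(self) -> None:
        expr = self.expression
        if isinstance(expr, ExpressionMatrix):
            if self.covariates is None:
                raise ValueError(
                    "raw ExpressionMatrix requires covariates for residualization"
                )
            expr = residualize(collapse_replicates(expr), self.covariates)
        g, e = align(self.genotypes, expr, min_group=self.min_group)
        self._aligned = (g, e)

    @property
    def aligned_genotypes(self) -> GenotypeMatrix:
        return self._aligned[0]

    @property
    def aligned_expression(self) -> ResidualExpressionMatrix:
        return self._aligned[1]

    def fit(self, tests=("veQTL", "eQTL")) -> QTLScanResults:
        g, e = self._aligned
        parts = []
        if "veQTL" in tests:
            parts.append(veqtl_scan(g, e, min_group=self.min_group))
        if "eQTL" in tests:
            parts.append(eqtl_scan(g, e))
        if not parts:
            raise ValueError("tests must include 'veQTL' and/or 'eQTL'")
        records = pd.concat(parts, ignore_index=True)
        if self.tissue is not None:
            records.insert(0, "tissue", self.tissue)
        return QTLScanResults(
            records,
            self.min_group,
            tissue=self.tissue,
            variant_meta=g.variant_meta,
            gene_meta=e.gene_meta,
        )
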