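"""Post-scan interpretation: significance, cis/trans, veQTL classes,
tissue-specificity, candidate filtering, and calibration diagnostics.

Significance uses a fixed genome-wide threshold (strict p < 5e-8) with no
multiple-testing correction by default; a Benjamini-Hochberg option is
available.  The cis window is +/- 1 Mb around the gene's annotated TSS
(inclusive boundary); anything farther, or on another chromosome, is
trans.

veQTL dispersion classes describe how the per-genotype-group mean
absolute deviation D_g varies with minor-allele dosage g:

* Class I   (recessive-like)    - the minor-homozygote group differs
  while the other two agree;
* Class II  (dosage-dependent)  - D strictly monotone in dosage with
  clear steps;
* Class III (heterozygote-like) - the heterozygote group differs while
  the homozygote groups agree.

The class rule uses a relative tolerance tau (default 0.25): two
dispersions a, b "agree" when |a - b| <= tau * max(a, b) and "differ"
when |a - b| > tau * max(a, b).  Pairs tested on only two genotype
groups cannot be placed (no minor-homozygote group) and are labelled
``unclassified``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("veqtl")

__all__ = [
    "call_significant", "bh_adjust", "annotate_cis_trans",
    "classify_veqtl", "classify_records",
    "tissue_specific_filter", "candidate_gene_filter",
    "genomic_inflation", "InflationReport", "rank_correlation",
    "significant_pairs",
]

GENOME_WIDE_P = 5e-8
CIS_WINDOW = 1_000_000
CHI2_1_MEDIAN = sps.chi2.ppf(0.5, 1)  # 0.4549...


def call_significant(records: pd.DataFrame, threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Flag records with p strictly below the threshold.

    Degenerate records (0/0 statistics, perfect fits) are never called
    significant regardless of their reported p.
    """
    rec = records.copy()
    p = rec["p"].to_numpy(dtype=float)
    sig = np.nan_to_num(p, nan=1.0) < threshold
    if "degenerate" in rec.columns:
        sig &= ~rec["degenerate"].to_numpy(dtype=bool)
    rec["significant"] = sig
    return rec


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def annotate_cis_trans(
    records: pd.DataFrame,
    variant_meta: pd.DataFrame,
    gene_meta: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Label each pair cis or trans relative to the gene's TSS.

    cis iff same chromosome and |variant_pos - TSS| <= window (boundary
    inclusive); otherwise trans.  Pairs with missing annotation are
    labelled ``unknown`` and logged; they are excluded from cis/trans
    tallies downstream.
    """
    rec = records.copy()
    vchrom = rec["variant_id"].map(variant_meta["chrom"])
    vpos = rec["variant_id"].map(variant_meta["pos"])
    gchrom = rec["gene_id"].map(gene_meta["chrom"])
    gtss = rec["gene_id"].map(gene_meta["tss"])
    known = vchrom.notna() & vpos.notna() & gchrom.notna() & gtss.notna()
    same = (vchrom == gchrom) & known
    dist = (vpos - gtss).abs()
    label = np.where(~known, "unknown", np.where(same & (dist <= window), "cis", "trans"))
    n_unknown = int((~known).sum())
    if n_unknown:
        log.warning("annotate_cis_trans: %d pairs lack coordinates; labelled unknown",
                    n_unknown)
    rec["cis_trans"] = label
    return rec


def _differ(a: float, b: float, tau: float) -> bool:
    m = max(a, b)
    if m == 0:
        return False
    return abs(a - b) > tau * m


def classify_veqtl(group_mad, groups_used, tolerance: float = 0.25) -> str:
    """Assign a dispersion class from per-genotype mean absolute deviations.

    Parameters
    ----------
    group_mad : mapping or sequence
        D_g for g = 0, 1, 2 (NaN / absent for unused groups).
    groups_used : iterable of int
        Genotype classes that entered the test.
    tolerance : float
        Relative tolerance tau for "agree"/"differ" comparisons.

    Returns one of ``"I"``, ``"II"``, ``"III"``, ``"unclassified"``,
    ``"not_applicable"``.  Only three-group tests are classifiable; the
    rules are checked in order II, I, III.
    """
    groups = sorted(int(g) for g in groups_used)
    if isinstance(group_mad, dict):
        d = [group_mad.get(g, math.nan) for g in (0, 1, 2)]
    else:
        d = [float(x) for x in group_mad]
    if any(not math.isfinite(d[g]) for g in groups):
        return "not_applicable"
    if groups != [0, 1, 2]:
        return "unclassified"
    d0, d1, d2 = d[0], d[1], d[2]

    monotone = (d0 < d1 < d2) or (d0 > d1 > d2)
    if monotone and _differ(d0, d1, tolerance) and _differ(d1, d2, tolerance):
        return "II"
    if _differ(d0, d2, tolerance) and not _differ(d0, d1, tolerance):
        return "I"
    if (_differ(d1, d0, tolerance) and _differ(d1, d2, tolerance)
            and not _differ(d0, d2, tolerance)):
        return "III"
    return "unclassified"


def classify_records(records: pd.DataFrame, tolerance: float = 0.25) -> pd.DataFrame:
    """Add a ``class_label`` column: classes for significant veQTL records,
    ``not_applicable`` for everything else."""
    rec = records.copy()
    labels = []
    for _, row in rec.iterrows():
        if row["test"] != "veQTL" or not row.get("significant", False):
            labels.append("not_applicable")
            continue
        groups = [int(x) for x in str(row["groups_used"]).split(",") if x != ""]
        mad = {g: row.get(f"mad_g{g}", math.nan) for g in (0, 1, 2)}
        labels.append(classify_veqtl(mad, groups, tolerance))
    rec["class_label"] = labels
    return rec


def significant_pairs(records: pd.DataFrame, threshold: float = GENOME_WIDE_P) -> set:
    """(variant_id, gene_id) pairs flagged significant (flagging if needed)."""
    rec = records
    if "significant" not in rec.columns:
        rec = call_significant(rec, threshold)
    sig = rec[rec["significant"]]
    return set(zip(sig["variant_id"], sig["gene_id"]))


def tissue_specific_filter(pairs_by_tissue: dict, focal_tissue: str) -> set:
    """Pairs significant in the focal tissue and in no other supplied tissue.

    ``pairs_by_tissue`` maps tissue label -> set of (variant, gene) pairs
    (or a records DataFrame, which is reduced to its significant pairs).
    """
    if focal_tissue not in pairs_by_tissue:
        raise ValueError(f"focal tissue {focal_tissue!r} not among supplied tissues "
                         f"{sorted(pairs_by_tissue)}")
    as_set = {
        t: (significant_pairs(v) if isinstance(v, pd.DataFrame) else set(v))
        for t, v in pairs_by_tissue.items()
    }
    focal = set(as_set[focal_tissue])
    for t, s in as_set.items():
        if t != focal_tissue:
            focal -= s
    return focal


def candidate_gene_filter(
    veqtl_by_tissue: dict,
    eqtl_focal: pd.DataFrame | set,
    focal_tissue: str,
    threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Candidate susceptibility pairs: focal-tissue veQTL, focal-only, not eQTL.

    Applies the three criteria in sequence: (i) significant veQTL in the
    focal tissue, (ii) significant in no other supplied tissue, (iii) the
    same pair is not a significant eQTL in the focal tissue.  Returns a
    table of surviving pairs sorted for deterministic output.
    """
    specific = tissue_specific_filter(veqtl_by_tissue, focal_tissue)
    eqtl_pairs = (
        significant_pairs(eqtl_focal, threshold)
        if isinstance(eqtl_focal, pd.DataFrame)
        else set(eqtl_focal)
    )
    kept = sorted(specific - eqtl_pairs)
    return pd.DataFrame(kept, columns=["variant_id", "gene_id"])


@dataclass
class InflationReport:
    """Genomic inflation factor with q-q data for one tissue/test."""

    lam: float
    n_tests: int
    expected: np.ndarray  # -log10 expected p, plotting positions (i-0.5)/n
    observed: np.ndarray  # -log10 observed p, sorted to match
    tissue: str | None = None
    test: str | None = None

    def qq_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"expected": self.expected, "observed": self.observed})


def genomic_inflation(p_values, tissue=None, test=None) -> InflationReport:
    """Median-based genomic inflation factor and q-q coordinates.

    lambda = median(qchisq(1 - p, df=1)) / qchisq(0.5, df=1): the ratio
    of the observed median association chi-square to its null
    expectation (0.4549).  Well-calibrated scans give lambda near 1.
    p = 0 entries are mapped to the largest representable quantile with a
    warning.  Expected q-q quantiles use plotting positions (i - 0.5)/n
    on the -log10 scale.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values for inflation estimate")
    n_zero = int((p == 0).sum())
    if n_zero:
        log.warning("genomic_inflation: %d zero p-values clamped to float minimum", n_zero)
    p_clamped = np.clip(p, np.finfo(float).tiny, 1.0)
    chi = sps.chi2.isf(p_clamped, 1)
    lam = float(np.median(chi) / CHI2_1_MEDIAN)
    n = p.size
    # both descending: smallest p (strongest signal) first, matching ranks
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.sort(p_clamped))
    return InflationReport(lam, n, expected, observed, tissue, test)


def rank_correlation(veqtl: pd.DataFrame, eqtl: pd.DataFrame) -> float:
    """Spearman correlation of -log10 p between the two scans.

    Computed over the (variant, gene) pairs present in both tables (ties
    mid-ranked, scipy convention).  Returns NaN when fewer than three
    pairs are shared.
    """
    key = ["variant_id", "gene_id"]
    merged = veqtl[key + ["p"]].merge(eqtl[key + ["p"]], on=key, suffixes=("_ve", "_e"))
    merged = merged.dropna()
    if len(merged) < 3:
        log.warning("rank_correlation: fewer than 3 shared pairs; undefined")
        return math.nan
    lv = -np.log10(np.clip(merged["p_ve"], np.finfo(float).tiny, 1.0))
    le = -np.log10(np.clip(merged["p_e"], np.finfo(float).tiny, 1.0))
    rho, _ = sps.spearmanr(lv, le)
    return float(rho)
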