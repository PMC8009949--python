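"""Significance calls, cis/trans labels, dispersion classes, tissue and
candidate filters, inflation factor and rank correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from veqtl.postprocess import (
    annotate_cis_trans,
    bh_adjust,
    call_significant,
    candidate_gene_filter,
    classify_veqtl,
    classify_records,
    genomic_inflation,
    rank_correlation,
    tissue_specific_filter,
)


def _records(rows):
    base = {"test": "veQTL", "degenerate": False}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestCallSignificant:
    def test_strict_threshold(self):
        rec = _records([
            {"variant_id": "v", "gene_id": "a", "p": 4.9e-8},
            {"variant_id": "v", "gene_id": "b", "p": 5e-8},
        ])
        out = call_significant(rec, 5e-8)
        assert bool(out.loc[0, "significant"])
        assert not bool(out.loc[1, "significant"])  # boundary is exclusive

    def test_degenerate_never_significant(self):
        rec = _records([
            {"variant_id": "v", "gene_id": "a", "p": 0.0, "degenerate": True},
        ])
        out = call_significant(rec)
        assert not bool(out.loc[0, "significant"])

    def test_nan_p_not_significant(self):
        rec = _records([{"variant_id": "v", "gene_id": "a", "p": math.nan}])
        assert not bool(call_significant(rec).loc[0, "significant"])


class TestCisTrans:
    VMETA = pd.DataFrame({"chrom": ["chr1", "chr1", "chr1"],
                          "pos": [1_000_000, 1_000_000, 5_000_000]},
                         index=["v1", "v2", "v3"])
    GMETA = pd.DataFrame({"chrom": ["chr1", "chr2", "chr1"],
                          "tss": [1_500_000, 1_500_000, 2_000_000]},
                         index=["gA", "gB", "gC"])

    def test_within_window_is_cis(self):
        rec = _records([{"variant_id": "v1", "gene_id": "gA", "p": 1e-9}])
        out = annotate_cis_trans(rec, self.VMETA, self.GMETA)
        assert out.loc[0, "cis_trans"] == "cis"

    def test_other_chromosome_is_trans(self):
        rec = _records([{"variant_id": "v1", "gene_id": "gB", "p": 1e-9}])
        out = annotate_cis_trans(rec, self.VMETA, self.GMETA)
        assert out.loc[0, "cis_trans"] == "trans"

    def test_exact_window_boundary_is_cis(self):
        rec = _records([{"variant_id": "v2", "gene_id": "gC", "p": 1e-9}])
        out = annotate_cis_trans(rec, self.VMETA, self.GMETA)
        assert out.loc[0, "cis_trans"] == "cis"  # |1e6 - 2e6| == window

    def test_beyond_window_is_trans(self):
        rec = _records([{"variant_id": "v3", "gene_id": "gA", "p": 1e-9}])
        out = annotate_cis_trans(rec, self.VMETA, self.GMETA)
        assert out.loc[0, "cis_trans"] == "trans"  # 3.5 Mb away, same chrom

    def test_missing_annotation_labelled_unknown(self):
        rec = _records([{"variant_id": "vX", "gene_id": "gA", "p": 1e-9}])
        out = annotate_cis_trans(rec, self.VMETA, self.GMETA)
        assert out.loc[0, "cis_trans"] == "unknown"


class TestClassifyVeqtl:
    @pytest.mark.parametrize("d, expected", [
        ((1.0, 1.0, 3.0), "I"),    # homozygote-recessive pattern
        ((1.0, 2.0, 4.0), "II"),   # dosage-dependent pattern
        ((1.0, 3.0, 1.0), "III"),  # heterozygote pattern
        ((3.0, 3.1, 3.05), "unclassified"),  # everything agrees
        ((4.0, 2.0, 1.0), "II"),   # decreasing dosage trend
        ((3.0, 1.0, 3.1), "III"),  # dip at the heterozygote
    ])
    def test_rule_table(self, d, expected):
        assert classify_veqtl(d, (0, 1, 2)) == expected

    def test_two_group_tests_unclassifiable(self):
        assert classify_veqtl({0: 1.0, 1: 3.0}, (0, 1)) == "unclassified"

    def test_missing_summaries_not_applicable(self):
        assert classify_veqtl((1.0, math.nan, 2.0), (0, 1, 2)) == "not_applicable"

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = tuple(rng.uniform(0.5, 5.0, 3))
            c = rng.uniform(0.1, 10.0)
            assert classify_veqtl(d, (0, 1, 2)) == \
                classify_veqtl(tuple(c * x for x in d), (0, 1, 2))

    def test_records_wrapper_only_labels_significant_veqtl(self):
        rec = _records([
            {"variant_id": "v", "gene_id": "a", "p": 1e-10, "groups_used": "0,1,2",
             "mad_g0": 1.0, "mad_g1": 1.0, "mad_g2": 3.0},
            {"variant_id": "v", "gene_id": "b", "p": 0.5, "groups_used": "0,1,2",
             "mad_g0": 1.0, "mad_g1": 1.0, "mad_g2": 3.0},
        ])
        out = classify_records(call_significant(rec))
        assert out.loc[0, "class_label"] == "I"
        assert out.loc[1, "class_label"] == "not_applicable"


class TestTissueAndCandidateFilters:
    def test_set_difference(self):
        got = tissue_specific_filter(
            {"breast": {("v1", "g1"), ("v2", "g2")}, "lung": {("v2", "g2")}},
            "breast",
        )
        assert got == {("v1", "g1")}

    def test_identity_without_other_tissues(self):
        got = tissue_specific_filter({"breast": {("v1", "g1")}}, "breast")
        assert got == {("v1", "g1")}

    def test_pair_in_all_tissues_excluded(self):
        got = tissue_specific_filter(
            {"breast": {("v", "g")}, "lung": {("v", "g")}, "ovary": {("v", "g")}},
            "breast",
        )
        assert got == set()

    def test_missing_focal_tissue_errors(self):
        with pytest.raises(ValueError, match="focal tissue"):
            tissue_specific_filter({"lung": set()}, "breast")

    def test_candidate_filter_three_criteria(self):
        ve = {
            "breast": {("v1", "gA"), ("v2", "gB"), ("v3", "gC")},
            "ovary": {("v2", "gB")},
        }
        eq = {("v3", "gC")}
        out = candidate_gene_filter(ve, eq, "breast")
        assert set(map(tuple, out.to_numpy())) == {("v1", "gA")}

    def test_monotone_adding_tissue_shrinks(self):
        ve = {"breast": {("v1", "gA"), ("v2", "gB")}}
        base = candidate_gene_filter(dict(ve), set(), "breast")
        ve["lung"] = {("v1", "gA")}
        smaller = candidate_gene_filter(ve, set(), "breast")
        assert set(map(tuple, smaller.to_numpy())) <= set(map(tuple, base.to_numpy()))

    def test_idempotent_and_order_independent(self):
        ve = {"breast": {("v1", "gA"), ("v2", "gB")}, "lung": {("v2", "gB")}}
        a = tissue_specific_filter(ve, "breast")
        b = tissue_specific_filter(dict(reversed(list(ve.items()))), "breast")
        assert a == b == tissue_specific_filter({"breast": a, "lung": ve["lung"]},
                                                "breast")


class TestGenomicInflation:
    def test_null_median_gives_unity(self):
        rep = genomic_inflation(np.full(101, 0.5))
        assert rep.lam == pytest.approx(1.0, abs=1e-12)

    def test_chi_square_quantile_oracle(self):
        # all p = 0.05: lambda = chi2_1(0.95) / chi2_1(0.5) = 3.8415/0.4549
        expected = sps.chi2.ppf(0.95, 1) / sps.chi2.ppf(0.5, 1)
        rep = genomic_inflation(np.full(11, 0.05))
        assert rep.lam == pytest.approx(expected, rel=1e-10)
        assert rep.lam == pytest.approx(8.44, abs=0.01)

    def test_uniform_grid_lambda_one(self):
        n = 10_000
        p = (np.arange(1, n + 1) - 0.5) / n
        assert genomic_inflation(p).lam == pytest.approx(1.0, abs=1e-3)

    def test_iid_uniform_lambda_near_one(self):
        rng = np.random.default_rng(12)
        lam = genomic_inflation(rng.uniform(size=10_000)).lam
        assert 0.95 < lam < 1.05

    def test_zero_p_clamped(self, caplog):
        rep = genomic_inflation([0.0, 0.5, 0.5])
        assert np.isfinite(rep.lam)

    def test_qq_vectors_match_length(self):
        rep = genomic_inflation(np.linspace(0.01, 0.99, 57))
        assert len(rep.expected) == len(rep.observed) == rep.n_tests == 57
        assert (np.diff(rep.expected) <= 0).all()
        assert (np.diff(rep.observed) <= 0).all()


class TestRankCorrelation:
    def _tables(self, p_ve, p_eq):
        keys = [("v", f"g{i}") for i in range(len(p_ve))]
        ve = pd.DataFrame({"variant_id": [k[0] for k in keys],
                           "gene_id": [k[1] for k in keys], "p": p_ve})
        eq = ve.copy()
        eq["p"] = p_eq
        return ve, eq

    def test_identical_vectors_give_one(self):
        p = np.linspace(1e-6, 0.9, 20)
        ve, eq = self._tables(p, p)
        assert rank_correlation(ve, eq) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        p = np.linspace(1e-6, 0.9, 20)
        ve, eq = self._tables(p, p[::-1])
        assert rank_correlation(ve, eq) == pytest.approx(-1.0)

    def test_independent_scans_near_zero(self):
        rng = np.random.default_rng(3)
        n = 2000
        ve, eq = self._tables(rng.uniform(size=n), rng.uniform(size=n))
        assert abs(rank_correlation(ve, eq)) < 3 / math.sqrt(n)

    def test_too_few_pairs_undefined(self):
        ve, eq = self._tables([0.1, 0.2], [0.3, 0.4])
        assert math.isnan(rank_correlation(ve, eq))


class TestBHAdjust:
    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
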