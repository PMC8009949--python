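"""Synthetic-data generator: Hardy-Weinberg draws, planted effects,
determinism and fixture round-trips."""

import numpy as np
import pandas as pd
import pytest

from veqtl import (
    EffectSpec,
    SimulationSpec,
    simulate_dataset,
    write_fixture,
)
from veqtl import io as vio
from veqtl.simulate import simulate_covariates, simulate_expression, simulate_genotypes
from veqtl.stats import brown_forsythe


class TestSpecValidation:
    def test_rejects_invalid_maf_naming_variant(self):
        with pytest.raises(ValueError, match="variant 1"):
            SimulationSpec(n_variants=3, maf=[0.3, 0.7, 0.2])

    def test_rejects_out_of_range_effect(self):
        with pytest.raises(ValueError, match="missing variant"):
            SimulationSpec(
                n_variants=2, n_genes=2,
                planted_effects=[EffectSpec(5, 0, "var_class_I", var_multiplier=2.0)],
            )
        with pytest.raises(ValueError, match="missing gene"):
            SimulationSpec(
                n_variants=2, n_genes=2,
                planted_effects=[EffectSpec(0, 7, "var_class_I", var_multiplier=2.0)],
            )

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            SimulationSpec(base_sd=0.0)
        with pytest.raises(ValueError):
            SimulationSpec(n_subjects=0)
        with pytest.raises(ValueError):
            EffectSpec(0, 0, "var_class_I", var_multiplier=0.5)
        with pytest.raises(ValueError):
            EffectSpec(0, 0, "no_such_kind")

    def test_null_effect_detection(self):
        assert EffectSpec(0, 0, "mean_additive", mean_beta=0.0).is_null
        assert EffectSpec(0, 0, "var_class_II", var_multiplier=1.0).is_null
        assert not EffectSpec(0, 0, "var_class_I", var_multiplier=2.0).is_null


class TestGenotypes:
    def test_hardy_weinberg_at_half(self):
        spec = SimulationSpec(n_subjects=10_000, n_variants=1, n_genes=1, maf=0.5, seed=1)
        g = simulate_genotypes(spec).calls.to_numpy()[:, 0]
        freqs = np.array([(g == c).mean() for c in (0, 1, 2)])
        # 3 binomial SDs around (0.25, 0.5, 0.25)
        sd = np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / 10_000)
        assert np.all(np.abs(freqs - [0.25, 0.5, 0.25]) < 3 * sd)

    def test_rare_allele_limit(self):
        spec = SimulationSpec(n_subjects=100, n_variants=1, n_genes=1, maf=1e-6, seed=2)
        g = simulate_genotypes(spec).calls.to_numpy()
        assert (g == 0).all()

    def test_column_mean_tracks_twice_maf(self):
        spec = SimulationSpec(n_subjects=5000, n_variants=4, n_genes=1,
                              maf=[0.1, 0.2, 0.3, 0.5], seed=3)
        g = simulate_genotypes(spec).calls.to_numpy()
        for j, f in enumerate([0.1, 0.2, 0.3, 0.5]):
            se = np.sqrt(2 * f * (1 - f) / 5000)
            assert abs(g[:, j].mean() - 2 * f) < 3 * se

    def test_deterministic_given_seed(self):
        spec = SimulationSpec(n_subjects=50, n_variants=3, n_genes=2, seed=9)
        a = simulate_genotypes(spec).calls
        b = simulate_genotypes(spec).calls
        pd.testing.assert_frame_equal(a, b)

    def test_adding_variants_keeps_earlier_columns(self):
        small = SimulationSpec(n_subjects=80, n_variants=2, n_genes=2, seed=4)
        big = SimulationSpec(n_subjects=80, n_variants=6, n_genes=2, seed=4)
        a = simulate_genotypes(small).calls
        b = simulate_genotypes(big).calls
        pd.testing.assert_frame_equal(a, b[a.columns])


class TestExpression:
    def test_planted_class_I_sd_ratio(self):
        """Group-2 vs group-0 sample SD recovers the planted multiplier."""
        m = 3.0
        spec = SimulationSpec(
            n_subjects=3000, n_variants=1, n_genes=1, maf=0.5, seed=5,
            replicate_rate=0.0, age_slope=0.0, sex_offset=0.0,
            planted_effects=[EffectSpec(0, 0, "var_class_I", var_multiplier=m)],
        )
        ds = simulate_dataset(spec)
        g = ds.genotypes.calls.to_numpy()[:, 0]
        y = ds.expression.values.to_numpy()[0]
        sd0, sd2 = y[g == 0].std(ddof=1), y[g == 2].std(ddof=1)
        n0, n2 = (g == 0).sum(), (g == 2).sum()
        ratio = sd2 / sd0
        # delta-method SE of an SD ratio under Gaussian sampling
        se = ratio * np.sqrt(1 / (2 * (n2 - 1)) + 1 / (2 * (n0 - 1)))
        assert abs(ratio - m) < 3 * se

    def test_class_II_sd_monotone_in_dosage(self):
        spec = SimulationSpec(
            n_subjects=900, n_variants=1, n_genes=1, maf=0.4, seed=6,
            replicate_rate=0.0,
            planted_effects=[EffectSpec(0, 0, "var_class_II", var_multiplier=2.0)],
        )
        ds = simulate_dataset(spec)
        g = ds.genotypes.calls.to_numpy()[:, 0]
        y = ds.expression.values.to_numpy()[0]
        sds = [y[g == c].std(ddof=1) for c in (0, 1, 2)]
        assert sds[0] < sds[1] < sds[2]

    def test_noise_free_mean_effect(self):
        """With base_sd -> 0 the genotype group means sit exactly beta apart."""
        spec = SimulationSpec(
            n_subjects=200, n_variants=1, n_genes=1, maf=0.4, seed=7,
            base_sd=1e-12, age_slope=0.0, sex_offset=0.0, replicate_rate=0.0,
            planted_effects=[EffectSpec(0, 0, "mean_additive", mean_beta=1.0)],
        )
        ds = simulate_dataset(spec)
        g = ds.genotypes.calls.to_numpy()[:, 0]
        y = ds.expression.values.to_numpy()[0]
        means = [y[g == c].mean() for c in (0, 1, 2)]
        assert means[1] - means[0] == pytest.approx(1.0, abs=1e-9)
        assert means[2] - means[1] == pytest.approx(1.0, abs=1e-9)

    def test_null_spec_group_variances_comparable(self):
        """All-null expression shows no detectable variance heterogeneity."""
        spec = SimulationSpec(n_subjects=600, n_variants=1, n_genes=30,
                              maf=0.5, seed=8, replicate_rate=0.0)
        ds = simulate_dataset(spec)
        g = ds.genotypes.calls.to_numpy()[:, 0]
        y = ds.expression.values.to_numpy()
        pvals = [
            brown_forsythe([y[j, g == c] for c in (0, 1, 2)]).p for j in range(30)
        ]
        # under the null at alpha=0.001 seeing any rejection in 30 tests is ~3%
        assert min(pvals) > 1e-4

    def test_non_negative_values(self):
        spec = SimulationSpec(n_subjects=100, n_variants=1, n_genes=5,
                              base_mean=0.0, seed=9)
        ds = simulate_dataset(spec)
        assert (ds.expression.values.to_numpy() >= 0).all()
        assert ds.offset > 0

    def test_replicated_subjects_get_two_samples(self):
        spec = SimulationSpec(n_subjects=100, n_variants=1, n_genes=2,
                              replicate_rate=0.2, seed=10)
        ds = simulate_dataset(spec)
        counts = ds.expression.sample_to_subject.value_counts()
        assert (counts == 2).sum() == 20
        assert (counts == 1).sum() == 80

    def test_expression_deterministic_and_stable_under_added_genes(self):
        base = SimulationSpec(n_subjects=60, n_variants=2, n_genes=3, seed=11)
        more = SimulationSpec(n_subjects=60, n_variants=2, n_genes=6, seed=11)
        a = simulate_dataset(base).expression.values
        b = simulate_dataset(more).expression.values
        # same noise streams per gene; only the global non-negativity shift
        # may differ, so compare after removing per-gene means
        ac = a.sub(a.mean(axis=1), axis=0)
        bc = b.loc[a.index].sub(b.loc[a.index].mean(axis=1), axis=0)
        pd.testing.assert_frame_equal(ac, bc)


class TestFixtureRoundTrip:
    def test_write_then_read_is_lossless(self, tmp_path):
        spec = SimulationSpec(
            n_subjects=40, n_variants=3, n_genes=4, seed=12, replicate_rate=0.25,
            planted_effects=[EffectSpec(0, 0, "var_class_III", var_multiplier=2.0)],
        )
        ds = simulate_dataset(spec)
        write_fixture(ds, tmp_path)
        g, e, c, manifest = vio.read_fixture(tmp_path)
        np.testing.assert_allclose(g.calls.to_numpy(), ds.genotypes.calls.to_numpy())
        np.testing.assert_allclose(e.values.to_numpy(), ds.expression.values.to_numpy())
        assert list(e.sample_to_subject) == list(ds.expression.sample_to_subject)
        pd.testing.assert_frame_equal(
            c.table, ds.covariates.table, check_exact=False, atol=1e-9,
            check_names=False,
        )
        assert manifest["spec"]["seed"] == 12
        assert len(manifest["spec"]["planted_effects"]) == 1

    def test_vcf_matches_tsv_coding(self, tmp_path):
        spec = SimulationSpec(n_subjects=30, n_variants=4, n_genes=2, seed=13)
        ds = simulate_dataset(spec)
        write_fixture(ds, tmp_path)
        from_vcf = vio.read_vcf(tmp_path / "genotypes.vcf")
        from_tsv = vio.read_genotype_tsv(tmp_path / "genotypes.tsv")
        np.testing.assert_allclose(
            from_vcf.calls.to_numpy(), from_tsv.calls.to_numpy()
        )

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = SimulationSpec(n_subjects=25, n_variants=2, n_genes=3, seed=14)
        write_fixture(simulate_dataset(spec), tmp_path / "a")
        write_fixture(simulate_dataset(SimulationSpec(**spec.to_dict())), tmp_path / "b")
        for name in ("genotypes.tsv", "expression.tsv", "covariates.tsv",
                     "manifest.yaml", "genotypes.vcf"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_empty_effect_list_recorded(self, tmp_path):
        spec = SimulationSpec(n_subjects=20, n_variants=1, n_genes=1, seed=15)
        write_fixture(simulate_dataset(spec), tmp_path)
        _, _, _, manifest = vio.read_fixture(tmp_path)
        assert manifest["spec"]["planted_effects"] == []
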