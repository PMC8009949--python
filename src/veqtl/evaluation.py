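"""Simulation-based validation of the scans.

Utilities that measure, on synthetic data, the properties the method is
supposed to have: agreement of the Brown-Forsythe implementation with an
independent median-centered Levene reference, type-I error calibration
and p-value uniformity under the Gaussian null, inflation-factor
behaviour on known inputs, and recovery of planted variance effects with
their dispersion-class labels.  These drive the acceptance checks and
are handy when recalibrating simulation parameters.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .scan import QTLScan
from .simulate import EffectSpec, SimulationSpec, simulate_dataset

__all__ = [
    "bf_oracle_comparison",
    "null_calibration",
    "effect_recovery",
    "mean_effect_control",
]

_CLASS_LABEL = {
    "var_class_I": "I",
    "var_class_II": "II",
    "var_class_III": "III",
}


def bf_oracle_comparison(n_instances: int = 1000, seed: int = 0) -> dict:
    """Compare `brown_forsythe` with scipy's median-centered Levene test.

    Random grouped datasets with k in {2, 3} and group sizes 2-30.
    Returns the maximum relative discrepancy of W and of p over all
    instances.
    """
    from .stats import brown_forsythe

    rng = np.random.default_rng(seed)
    worst_w = worst_p = 0.0
    for _ in range(n_instances):
        k = int(rng.integers(2, 4))
        groups = [rng.normal(size=int(rng.integers(2, 31))) for _ in range(k)]
        mine = brown_forsythe(groups)
        with np.errstate(divide="ignore", invalid="ignore"):
            w_ref, p_ref = sps.levene(*groups, center="median")
        if not np.isfinite(w_ref):
            # zero within-group deviation sum (e.g. all groups of size 2):
            # both implementations must agree the ratio blows up
            assert mine.degenerate or mine.statistic == 0.0
            continue
        worst_w = max(worst_w, abs(mine.statistic - w_ref) / max(abs(w_ref), 1e-300))
        worst_p = max(worst_p, abs(mine.p - p_ref) / max(p_ref, 1e-300))
    return {"max_rel_error_w": worst_w, "max_rel_error_p": worst_p,
            "n": n_instances}


def _scan_null(n_tests: int, n_subjects: int, maf: float, seed: int):
    spec = SimulationSpec(
        n_subjects=n_subjects, n_variants=1, n_genes=n_tests, maf=maf,
        seed=seed, replicate_rate=0.0,
    )
    ds = simulate_dataset(spec)
    model = QTLScan(ds.genotypes, ds.expression, covariates=ds.covariates)
    return model.fit(tests=("veQTL",)).veqtl["p"].to_numpy()


def null_calibration(
    n_tests: int = 10_000, n_subjects: int = 300, maf: float = 0.3, seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error and p-value uniformity of the variance scan under the null.

    One Gaussian-null dataset of ``n_tests`` genes is scanned against a
    single Hardy-Weinberg variant; each gene carries independent noise so
    the tests are conditionally independent given the genotype draw.
    """
    p = _scan_null(n_tests, n_subjects, maf, seed)
    ks = sps.kstest(p, "uniform")
    from .postprocess import genomic_inflation

    return {
        "type1_rate": float((p < alpha).mean()),
        "alpha": alpha,
        "ks_pvalue": float(ks.pvalue),
        "lambda": genomic_inflation(p).lam,
        "n": int(p.size),
    }


def effect_recovery(
    kind: str,
    multiplier: float = 3.0,
    n_subjects: int = 500,
    maf: float = 0.3,
    n_replicates: int = 200,
    n_variants: int = 10,
    seed: int = 0,
    threshold: float = 5e-8,
    tolerance: float = 0.25,
) -> dict:
    """Power and class-label accuracy for one planted variance-effect kind.

    ``n_replicates`` genes each carry the effect (spread over
    ``n_variants`` independent genotype draws); power is the fraction of
    planted pairs reaching the significance threshold, and label accuracy
    the fraction of those significant pairs assigned the planted class.
    """
    effects = [
        EffectSpec(j % n_variants, j, kind, var_multiplier=multiplier)
        for j in range(n_replicates)
    ]
    spec = SimulationSpec(
        n_subjects=n_subjects, n_variants=n_variants, n_genes=n_replicates,
        maf=maf, seed=seed, replicate_rate=0.0, planted_effects=effects,
    )
    ds = simulate_dataset(spec)
    model = QTLScan(ds.genotypes, ds.expression, covariates=ds.covariates)
    res = model.fit(tests=("veQTL",)).call_significant(threshold).classify(tolerance)
    rec = res.records.set_index(["variant_id", "gene_id"])
    planted = [
        (f"var{e.variant_index:04d}", f"gene{e.gene_index:04d}") for e in effects
    ]
    rows = rec.loc[[p for p in planted if p in rec.index]]
    sig = rows[rows["significant"]]
    power = len(sig) / n_replicates
    want = _CLASS_LABEL[kind]
    label_acc = float((sig["class_label"] == want).mean()) if len(sig) else float("nan")
    return {"power": power, "label_accuracy": label_acc,
            "n": n_replicates, "n_significant": int(len(sig))}


def mean_effect_control(
    beta: float = 1.0,
    n_subjects: int = 500,
    maf: float = 0.3,
    n_replicates: int = 200,
    n_variants: int = 10,
    seed: int = 0,
    threshold: float = 5e-8,
) -> dict:
    """Planted pure-mean effects: eQTL power and spurious veQTL hit count.

    A shift in group means must be detected by the regression scan but
    leave the median-centered variance statistic at its null rate.
    """
    effects = [
        EffectSpec(j % n_variants, j, "mean_additive", mean_beta=beta)
        for j in range(n_replicates)
    ]
    spec = SimulationSpec(
        n_subjects=n_subjects, n_variants=n_variants, n_genes=n_replicates,
        maf=maf, seed=seed, replicate_rate=0.0, planted_effects=effects,
    )
    ds = simulate_dataset(spec)
    model = QTLScan(ds.genotypes, ds.expression, covariates=ds.covariates)
    res = model.fit().call_significant(threshold)
    planted = {
        (f"var{e.variant_index:04d}", f"gene{e.gene_index:04d}") for e in effects
    }
    eq = res.eqtl
    eq_hits = set(zip(eq[eq["significant"]]["variant_id"],
                      eq[eq["significant"]]["gene_id"]))
    ve = res.veqtl
    ve_hits = set(zip(ve[ve["significant"]]["variant_id"],
                      ve[ve["significant"]]["gene_id"]))
    return {
        "eqtl_power": len(eq_hits & planted) / n_replicates,
        "veqtl_hits_on_planted": len(ve_hits & planted),
        "n": n_replicates,
    }
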