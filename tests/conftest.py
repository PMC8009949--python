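"""Shared fixtures: a hand-built toy dataset with enumerable expected
outcomes, and a small simulated dataset for integration-style tests."""

import numpy as np
import pandas as pd
import pytest

from veqtl import (
    CovariateTable,
    EffectSpec,
    ExpressionMatrix,
    GenotypeMatrix,
    SimulationSpec,
    simulate_dataset,
)

N_TOY_SUBJECTS = 300


def _column_from_counts(c0: int, c1: int, c2: int) -> np.ndarray:
    assert c0 + c1 + c2 == N_TOY_SUBJECTS
    return np.array([0.0] * c0 + [1.0] * c1 + [2.0] * c2)


# per-variant genotype class counts and the filtering outcome they force
TOY_VARIANT_COUNTS = {
    "v1": (200, 60, 40),   # all three classes testable
    "v2": (200, 91, 9),    # two-group fallback on classes 0,1
    "v3": (291, 5, 4),     # only one class >= 10 -> dropped
    "v4": (300, 0, 0),     # monomorphic -> dropped
    "v5": (251, 40, 9),    # retained, fallback on classes 0,1
    "v6": (150, 140, 10),  # boundary: minor-homozygote class exactly 10
}
TOY_EXPECTED_VARIANTS = ["v1", "v2", "v5", "v6"]
TOY_EXPECTED_GROUPS = {"v1": "0,1,2", "v2": "0,1", "v5": "0,1", "v6": "0,1,2"}


@pytest.fixture(scope="session")
def toy_genotypes() -> GenotypeMatrix:
    calls = pd.DataFrame(
        {vid: _column_from_counts(*cnt) for vid, cnt in TOY_VARIANT_COUNTS.items()},
        index=[f"S{i:03d}" for i in range(N_TOY_SUBJECTS)],
    )
    meta = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr3"],
            "pos": [1_000_000, 2_000_000, 3_000_000, 1_000_000, 5_000_000, 1_500_000],
            "ref": "A",
            "alt": "G",
        },
        index=list(TOY_VARIANT_COUNTS),
    )
    return GenotypeMatrix(calls, meta)


# 12 genes x 60 samples with expression patterns pinned to the RPKM filter
# rule (> 0.1 in >= 10 samples)
N_TOY_SAMPLES = 60
TOY_GENE_PATTERNS = {
    "g01": (1.0, 60),    # expressed everywhere      -> keep
    "g02": (0.2, 10),    # boundary: exactly 10      -> keep
    "g03": (0.2, 9),     # one sample short          -> drop
    "g04": (0.1, 50),    # exactly at the floor      -> drop (strict >)
    "g05": (0.11, 10),   # just above the floor      -> keep
    "g06": (0.0, 0),     # silent                    -> drop
    "g07": (5.0, 60),    # high everywhere           -> keep
    "g08": (0.1, 60),    # at the floor everywhere   -> drop
    "g09": (0.2, 11),    # one above boundary        -> keep
    "g10": (0.15, 9),    # too few above-floor       -> drop
    "g11": (2.0, 20),    # expressed in a subset     -> keep
    "g12": (1.0, 10),    # boundary again            -> keep
}
TOY_EXPECTED_GENES = ["g01", "g02", "g05", "g07", "g09", "g11", "g12"]


@pytest.fixture(scope="session")
def toy_expression() -> ExpressionMatrix:
    samples = [f"S{i:03d}-s1" for i in range(N_TOY_SAMPLES)]
    rows = {}
    for gid, (value, n_on) in TOY_GENE_PATTERNS.items():
        row = np.zeros(N_TOY_SAMPLES)
        row[:n_on] = value
        rows[gid] = row
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    mapping = pd.Series([s.split("-")[0] for s in samples], index=samples)
    gene_meta = pd.DataFrame(
        {
            "chrom": ["chr1"] * 6 + ["chr2"] * 3 + ["chr3"] * 3,
            "tss": [1_500_000, 2_000_000, 500_000, 4_000_000, 9_000_000, 100_000,
                    1_000_000, 2_000_000, 8_000_000, 1_400_000, 2_500_000, 90_000_000],
            "strand": ["+", "-"] * 6,
        },
        index=list(TOY_GENE_PATTERNS),
    )
    return ExpressionMatrix(values, mapping, gene_meta)


@pytest.fixture(scope="session")
def toy_covariates() -> CovariateTable:
    subjects = [f"S{i:03d}" for i in range(N_TOY_SUBJECTS)]
    rng = np.random.default_rng(42)
    tbl = pd.DataFrame(
        {"age": rng.uniform(20, 70, N_TOY_SUBJECTS),
         "sex": np.tile([0, 1], N_TOY_SUBJECTS // 2)},
        index=subjects,
    )
    return CovariateTable(tbl)


@pytest.fixture(scope="session")
def planted_dataset():
    """Mid-sized simulation with one effect of each kind, for scan tests."""
    spec = SimulationSpec(
        n_subjects=400,
        n_variants=5,
        n_genes=20,
        maf=0.3,
        seed=2024,
        planted_effects=[
            EffectSpec(0, 0, "var_class_I", var_multiplier=4.0),
            EffectSpec(1, 1, "var_class_II", var_multiplier=3.0),
            EffectSpec(2, 2, "var_class_III", var_multiplier=4.0),
            EffectSpec(3, 3, "mean_additive", mean_beta=1.5),
        ],
    )
    return simulate_dataset(spec)
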