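"""Shared fixtures: small summary-statistic files and one modest synthetic
study reused across test modules (session-scoped; everything is generated at
test time from fixed seeds)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crosstrait.simulate import ArchitectureSpec, simulate_study

SMALL_SPEC = ArchitectureSpec(
    m_snps=1500,
    n_blocks=150,
    n_gwas_a=6000,
    n_gwas_b=6000,
    n_gwas_c=4000,
    n_reference=500,
    n_patient_cases=300,
    n_patient_controls=300,
)


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end synthetic study shared by integration tests."""
    return simulate_study(SMALL_SPEC, seed=11)


@pytest.fixture
def sumstats_frame():
    """Five clean summary-statistic records."""
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(1, 6)],
            "chrom": ["1", "1", "2", "2", "3"],
            "pos": [100, 200, 100, 250, 500],
            "effect_allele": ["A", "C", "G", "T", "A"],
            "other_allele": ["G", "T", "A", "C", "C"],
            "eaf": [0.1, 0.25, 0.4, 0.3, 0.45],
            "beta": [0.05, -0.02, 0.0, 0.11, -0.3],
            "se": [0.01, 0.02, 0.05, 0.04, 0.1],
            "pvalue": [1e-6, 0.32, 1.0, 0.006, 0.0027],
            "n_eff": [1000.0, 1000.0, 900.0, 800.0, 1000.0],
        }
    )


@pytest.fixture
def sumstats_file(tmp_path, sumstats_frame):
    """Factory writing a (possibly modified) summary-stat file to disk."""

    def write(df=None, name="stats.tsv", **edits):
        df = (sumstats_frame if df is None else df).copy()
        for col, values in edits.items():
            df[col] = values
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return write


def rng_for(test_name: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(abs(hash((test_name, salt))) % 2**31)
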