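"""Shared I/O for the numbered analysis scripts.

Script 01 generates the synthetic study and writes every artifact as plain
text under results/data/; later scripts reload from disk so each step reads
only the previous steps' outputs. The study scale here is the analysis
default (desk scale: 6,000 SNPs in 600 LD blocks, 10k GWAS cohorts, 2,000
patients), chosen so the full numbered sequence runs in a few minutes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from crosstrait.ld import GenotypePanel, read_matrix_panel, write_matrix_panel
from crosstrait.pgs import CohortData
from crosstrait.simulate import ArchitectureSpec
from crosstrait.sumstats import CaseControlDesign, read_sumstats, write_sumstats

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

ANALYSIS_SPEC = ArchitectureSpec(
    m_snps=6_000,
    n_blocks=600,
    n_gwas_a=10_000,
    n_gwas_b=10_000,
    n_gwas_c=8_000,
    n_reference=500,
    n_patient_cases=1_000,
    n_patient_controls=1_000,
)
SEED = 2024


def write_study(sim) -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    write_sumstats(sim.gwas_a, DATA / "gwas_proxy.tsv")
    write_sumstats(sim.gwas_b, DATA / "gwas_target.tsv")
    write_sumstats(sim.gwas_c, DATA / "gwas_shared.tsv")
    write_matrix_panel(sim.panel, DATA / "panel.tsv", DATA / "panel_variants.tsv")
    write_matrix_panel(
        sim.patients.genotypes,
        DATA / "patients_genotypes.tsv",
        DATA / "patients_variants.tsv",
    )
    sim.patients.phenotypes.to_csv(
        DATA / "patients_phenotypes.tsv", sep="\t", index=False
    )
    sim.truth.to_csv(DATA / "truth.tsv", sep="\t", index=False)


def load_sumstats(name: str, design: CaseControlDesign | None = None):
    table, _ = read_sumstats(DATA / f"{name}.tsv", trait_label=name, design=design)
    return table


def load_panel() -> GenotypePanel:
    return read_matrix_panel(DATA / "panel.tsv", DATA / "panel_variants.tsv")


def load_patients() -> CohortData:
    genotypes = read_matrix_panel(
        DATA / "patients_genotypes.tsv", DATA / "patients_variants.tsv"
    )
    pheno = pd.read_csv(DATA / "patients_phenotypes.tsv", sep="\t")
    return CohortData(genotypes, pheno)


def load_truth() -> pd.DataFrame:
    return pd.read_csv(DATA / "truth.tsv", sep="\t", dtype={"chrom": str})


def target_design() -> CaseControlDesign:
    half = ANALYSIS_SPEC.n_gwas_b // 2
    return CaseControlDesign(half, ANALYSIS_SPEC.n_gwas_b - half)


def require_study() -> None:
    if not (DATA / "gwas_proxy.tsv").exists():
        raise SystemExit(
            "study inputs missing; run analysis/01_simulate_study.py first"
        )
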