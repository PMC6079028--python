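"""Synthetic study generator: genotype structure, mixture architecture,
liability phenotypes, GWAS scan calibration, and assortative mating."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crosstrait import simulate as sim
from crosstrait.simulate import ArchitectureSpec

SPEC = ArchitectureSpec(m_snps=800, n_blocks=80, n_reference=300)


def small_genotypes(n=2000, seed=0, spec=SPEC):
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    variants = sim.make_variants(spec, np.random.default_rng(s1))
    dosages, _ = sim.simulate_genotypes(spec, n, s2, variants=variants)
    return dosages, variants


class TestGenotypes:
    def test_same_seed_identical_panel(self):
        d1, v1 = small_genotypes(seed=3)
        d2, v2 = small_genotypes(seed=3)
        assert np.array_equal(d1, d2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_empirical_maf_tracks_spec(self):
        dosages, variants = small_genotypes(n=4000, seed=4)
        emp = dosages.mean(axis=0) / 2.0
        maf = variants["maf"].to_numpy()
        se = np.sqrt(maf * (1 - maf) / (2 * 4000))
        within = np.abs(emp - maf) <= 4 * se
        assert within.mean() > 0.99

    def test_zero_block_r_gives_independent_snps(self):
        spec = ArchitectureSpec(
            m_snps=100, n_blocks=10, within_block_r=0.0, n_reference=100
        )
        dosages, _ = small_genotypes(n=4000, seed=5, spec=spec)
        X = (dosages - dosages.mean(0)) / dosages.std(0)
        corr = X.T @ X / len(X)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.mean(off**2) < 2.5 / 4000  # ~1/n under independence

    def test_within_block_ld_exceeds_between_block_ld(self):
        dosages, variants = small_genotypes(n=2000, seed=6)
        X = (dosages - dosages.mean(0)) / np.maximum(dosages.std(0), 1e-9)
        blocks = variants["block"].to_numpy()
        corr = X.T @ X / len(X)
        same = []
        diff = []
        rng = np.random.default_rng(0)
        for _ in range(3000):
            i, j = rng.integers(0, len(blocks), 2)
            if i == j:
                continue
            (same if blocks[i] == blocks[j] else diff).append(corr[i, j] ** 2)
        assert np.mean(same) > 10 * np.mean(diff)


class TestDrawEffects:
    def test_symmetric_mixture_implies_zero_correlation(self):
        spec = ArchitectureSpec(m_snps=50_000, n_blocks=5_000)
        truth = sim.draw_effects(spec, 1, sim.make_variants(spec, np.random.default_rng(0)))
        a, b = truth["beta_a"].to_numpy(), truth["beta_b"].to_numpy()
        emp = np.corrcoef(a, b)[0, 1]
        assert spec.implied_rg() == 0.0
        assert abs(emp) < 0.05

    def test_one_sided_mixture_implies_positive_correlation(self):
        spec = ArchitectureSpec(
            m_snps=50_000, n_blocks=5_000, f_concordant=0.04, f_discordant=0.0
        )
        truth = sim.draw_effects(spec, 2, sim.make_variants(spec, np.random.default_rng(1)))
        emp = np.corrcoef(truth["beta_a"], truth["beta_b"])[0, 1]
        implied = spec.implied_rg()
        assert implied > 0
        assert emp == pytest.approx(implied, abs=0.05)

    def test_genic_variance_matches_h2(self):
        spec = ArchitectureSpec(m_snps=20_000, n_blocks=2_000)
        truth = sim.draw_effects(spec, 3, sim.make_variants(spec, np.random.default_rng(2)))
        assert (truth["beta_a"] ** 2).sum() == pytest.approx(spec.h2_a, rel=0.15)
        assert (truth["beta_b"] ** 2).sum() == pytest.approx(spec.h2_b, rel=0.15)
        assert (truth["beta_c"] ** 2).sum() == pytest.approx(spec.h2_c, rel=0.15)

    def test_class_sign_structure(self):
        spec = ArchitectureSpec(m_snps=10_000, n_blocks=1_000)
        truth = sim.draw_effects(spec, 4, sim.make_variants(spec, np.random.default_rng(3)))
        conc = truth[truth["class"] == "concordant"]
        disc = truth[truth["class"] == "discordant"]
        assert (np.sign(conc["beta_a"]) == np.sign(conc["beta_b"])).all()
        assert (np.sign(disc["beta_a"]) == -np.sign(disc["beta_b"])).all()
        spa = truth[truth["class"] == "specific_a"]
        assert (spa["beta_b"] == 0).all()
        assert (spa["beta_a"] != 0).all()


class TestPhenotypes:
    def test_case_fraction_tracks_prevalence(self):
        dosages, variants = small_genotypes(n=6000, seed=7)
        truth = sim.draw_effects(SPEC, 5, variants)
        pheno = sim.simulate_phenotypes(dosages, truth, SPEC, 8)
        k = SPEC.prevalence_k
        frac = pheno["case_b"].mean()
        assert abs(frac - k) < 4 * np.sqrt(k * (1 - k) / 6000)

    def test_null_heritability_gives_flat_regression(self):
        spec = ArchitectureSpec(
            m_snps=400, n_blocks=40, h2_a=0.0, h2_b=0.0, h2_c=0.0, n_reference=100
        )
        dosages, variants = small_genotypes(n=2000, seed=9, spec=spec)
        truth = sim.draw_effects(spec, 10, variants)
        pheno = sim.simulate_phenotypes(dosages, truth, spec, 11)
        assert (truth["beta_a"] == 0).all()
        g = dosages[:, :50].astype(float)
        slopes = np.cov(pheno["trait_a"], g.T)[0, 1:] / g.var(axis=0)
        assert np.abs(slopes).mean() < 0.05

    def test_trait_a_regression_on_genic_value_is_unit_slope(self):
        dosages, variants = small_genotypes(n=4000, seed=12)
        truth = sim.draw_effects(SPEC, 13, variants)
        pheno = sim.simulate_phenotypes(dosages, truth, SPEC, 14)
        g = sim._genic_values(dosages, truth, "beta_a")
        slope = np.cov(pheno["trait_a"], g)[0, 1] / g.var()
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_symptoms_only_for_cases(self):
        dosages, variants = small_genotypes(n=3000, seed=15)
        truth = sim.draw_effects(SPEC, 16, variants)
        pheno = sim.simulate_phenotypes(dosages, truth, SPEC, 17)
        case = pheno["case_b"].astype(bool)
        assert pheno.loc[~case, "symptom_het"].isna().all()
        assert pheno.loc[case, "symptom_het"].notna().all()


class TestRunGwas:
    def test_null_snp_pvalues_uniform(self):
        dosages, variants = small_genotypes(n=3000, seed=18)
        truth = sim.draw_effects(SPEC, 19, variants)
        rng = np.random.default_rng(20)
        y = rng.normal(size=3000)  # phenotype unrelated to genotypes
        table = sim.run_gwas(dosages, variants, y, "linear")
        assert sps.kstest(table.df["pvalue"], "uniform").pvalue > 0.01

    def test_causal_chisq_exceeds_null_chisq(self, small_sim):
        truth = small_sim.truth.set_index("snp_id")
        chi = pd.Series(small_sim.gwas_b.chisq(), index=small_sim.gwas_b.df["snp_id"])
        causal = truth["beta_b"] != 0
        assert chi[causal].mean() > chi[~causal].mean()

    def test_disjoint_cohorts_replicate_causal_effects(self):
        spec = ArchitectureSpec(m_snps=800, n_blocks=80, n_reference=100)
        variants = sim.make_variants(spec, np.random.default_rng(21))
        truth = sim.draw_effects(spec, 22, variants)
        tables = []
        for seed in (23, 24):
            dosages, _ = sim.simulate_genotypes(spec, 5000, seed, variants=variants)
            pheno = sim.simulate_phenotypes(dosages, truth, spec, seed + 100)
            tables.append(sim.run_gwas(dosages, variants, pheno["trait_a"].to_numpy(), "linear"))
        causal = (truth["beta_a"] != 0).to_numpy()
        b1 = tables[0].df["beta"].to_numpy()[causal]
        b2 = tables[1].df["beta"].to_numpy()[causal]
        assert np.corrcoef(b1, b2)[0, 1] > 0.3

    def test_case_control_scan_recovers_liability_direction(self):
        spec = ArchitectureSpec(m_snps=600, n_blocks=60, n_reference=100)
        variants = sim.make_variants(spec, np.random.default_rng(25))
        truth = sim.draw_effects(spec, 26, variants)
        dosages, pheno = sim.simulate_case_control_cohort(
            spec, truth, variants, 1500, 1500, 27
        )
        table = sim.run_gwas(
            dosages, variants, pheno["case_b"].to_numpy(), "case_control"
        )
        causal = truth["beta_b"] != 0
        big = causal & (truth["beta_b"].abs() > truth.loc[causal, "beta_b"].abs().median())
        sign_match = np.sign(table.df.loc[big.to_numpy(), "beta"]) == np.sign(
            truth.loc[big.to_numpy(), "beta_b"]
        )
        assert sign_match.mean() > 0.8

    def test_monomorphic_snps_flagged_and_dropped(self):
        dosages, variants = small_genotypes(n=500, seed=28)
        dosages = dosages.copy()
        dosages[:, 0] = 1  # force monomorphic
        y = np.random.default_rng(29).normal(size=500)
        table = sim.run_gwas(dosages, variants, y, "linear")
        assert variants["snp_id"].iloc[0] in table.df.attrs["monomorphic"]
        assert variants["snp_id"].iloc[0] not in set(table.df["snp_id"])


class TestStudyAssembly:
    def test_patient_cohort_composition(self, small_sim):
        pheno = small_sim.patients.phenotypes
        assert pheno["case_b"].sum() == small_sim.spec.n_patient_cases
        assert (1 - pheno["case_b"]).sum() == small_sim.spec.n_patient_controls
        assert {"pc1", "age_of_onset", "medication"} <= set(pheno.columns)
        case = pheno["case_b"].astype(bool)
        assert pheno.loc[case, "age_of_onset"].notna().all()
        assert pheno.loc[~case, "age_of_onset"].isna().all()

    def test_gwas_tables_cover_panel_variants(self, small_sim):
        assert set(small_sim.gwas_a.snp_ids) <= set(
            small_sim.panel.variants["snp_id"]
        )
        assert small_sim.gwas_b.design is not None
        assert small_sim.gwas_b.design.n_total == small_sim.spec.n_gwas_b


class TestAssortativeMating:
    def _setup(self, seed=30, n=3000):
        spec = ArchitectureSpec(m_snps=400, n_blocks=40, n_reference=100)
        variants = sim.make_variants(spec, np.random.default_rng(seed))
        truth = sim.draw_effects(spec, seed + 1, variants)
        dosages, _ = sim.simulate_genotypes(spec, n, seed + 2, variants=variants)
        return spec, variants, truth, dosages

    def test_reproducible_offspring(self):
        spec, variants, truth, dosages = self._setup()
        out1 = sim.assortative_mating(dosages, truth, spec, 0.5, 1, seed=7)
        out2 = sim.assortative_mating(dosages, truth, spec, 0.5, 1, seed=7)
        assert np.array_equal(out1[0], out2[0])

    def test_random_mating_preserves_genic_variance(self):
        spec, variants, truth, dosages = self._setup(seed=40)
        g0 = sim._genic_values(dosages, truth, "beta_a").var()
        new_dos, _ = sim.assortative_mating(dosages, truth, spec, 0.0, 2, seed=8)
        g2 = sim._genic_values(new_dos, truth, "beta_a").var()
        assert g2 == pytest.approx(g0, rel=0.35)

    def test_assortment_inflates_genic_variance(self):
        """Positive assortment on a heritable trait builds gametic-phase
        disequilibrium, raising the trait's genic variance across
        generations (classical expectation, checked directionally)."""
        spec = ArchitectureSpec(
            m_snps=400, n_blocks=40, h2_a=0.8, n_reference=100
        )
        variants = sim.make_variants(spec, np.random.default_rng(50))
        truth = sim.draw_effects(spec, 51, variants)
        base, am = [], []
        for seed in range(6):
            dosages, _ = sim.simulate_genotypes(spec, 4000, 60 + seed, variants=variants)
            g0 = sim._genic_values(dosages, truth, "beta_a").var()
            dos_am, _ = sim.assortative_mating(
                dosages, truth, spec, 0.8, 3, seed=70 + seed
            )
            g_am = sim._genic_values(dos_am, truth, "beta_a").var()
            base.append(g0)
            am.append(g_am)
        assert np.mean(am) > np.mean(base)

    def test_odd_cohort_trimmed_with_warning(self, caplog):
        spec, variants, truth, dosages = self._setup(seed=80, n=301)
        with caplog.at_level("WARNING"):
            new_dos, _ = sim.assortative_mating(dosages, truth, spec, 0.2, 1, seed=9)
        assert new_dos.shape[0] == 300
        assert any("odd cohort" in r.message for r in caplog.records)
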