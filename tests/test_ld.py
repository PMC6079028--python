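"""LD panel operations: r², clumping (against a brute-force oracle), proxy
search, LD partners, LD scores, and panel I/O."""

import numpy as np
import pandas as pd
import pytest

from crosstrait import ld
from crosstrait.simulate import ArchitectureSpec, make_variants, simulate_genotypes
from crosstrait.sumstats import SumStats


def toy_panel(dosages, positions=None, chrom=None):
    m = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "snp_id": [f"v{i}" for i in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
    return ld.GenotypePanel(np.asarray(dosages, dtype=float), variants)


def blocky_panel(seed, m_snps=40, n_blocks=8, n=300):
    spec = ArchitectureSpec(
        m_snps=m_snps, n_blocks=n_blocks, n_reference=n,
        block_spacing_bp=50_000, snp_spacing_bp=1_000,
    )
    rng = np.random.default_rng(seed)
    variants = make_variants(spec, rng)
    dosages, _ = simulate_genotypes(spec, n, seed + 1, variants=variants)
    return ld.GenotypePanel(
        dosages.astype(float),
        variants[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy(),
    )


class TestPairwiseR2:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        panel = toy_panel(rng.integers(0, 3, (50, 3)))
        assert ld.pairwise_r2(panel, "v0", "v0") == pytest.approx(1.0)

    def test_matches_brute_force_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 200).astype(float)
        y = x.copy()
        y[0] = 2 - y[0] if y[0] != 1 else 0  # perturb one dosage
        panel = toy_panel(np.column_stack([x, y]))
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert ld.pairwise_r2(panel, "v0", "v1") == pytest.approx(expected)

    def test_independent_snps_have_tiny_r2(self):
        rng = np.random.default_rng(2)
        panel = toy_panel(rng.binomial(2, 0.4, size=(10_000, 2)))
        assert ld.pairwise_r2(panel, "v0", "v1") < 0.01

    def test_monomorphic_snp_raises(self):
        panel = toy_panel(np.column_stack([np.ones(30), np.arange(30) % 3]))
        with pytest.raises(ld.LdError):
            ld.pairwise_r2(panel, "v0", "v1")

    def test_pairwise_complete_handles_missing(self):
        x = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 2], dtype=float)
        y = x.copy()
        y[3] = np.nan
        panel = toy_panel(np.column_stack([x, y]))
        ok = ~np.isnan(y)
        expected = np.corrcoef(x[ok], y[ok])[0, 1] ** 2
        assert ld.pairwise_r2(panel, "v0", "v1") == pytest.approx(expected)


def brute_force_clump(sumstats, panel, p_threshold, r2_threshold, window_kb):
    """Literal greedy reference implementation using only pairwise_r2."""
    df = sumstats.df
    rows = df.sort_values("pvalue", kind="stable").to_dict("records")
    assigned: set[str] = set()
    leads, membership = [], {}
    for rec in rows:
        if rec["snp_id"] in assigned or rec["pvalue"] >= p_threshold:
            continue
        lead = rec["snp_id"]
        leads.append(lead)
        assigned.add(lead)
        membership[lead] = lead
        if lead not in panel:
            continue
        for other in df.to_dict("records"):
            sid = other["snp_id"]
            if sid in assigned or sid not in panel:
                continue
            if other["chrom"] != rec["chrom"]:
                continue
            if abs(other["pos"] - rec["pos"]) > window_kb * 1000:
                continue
            try:
                r2 = ld.pairwise_r2(panel, lead, sid)
            except ld.LdError:
                continue
            if r2 > r2_threshold:
                assigned.add(sid)
                membership[sid] = lead
    return leads, membership


class TestLdClump:
    def test_matches_brute_force_over_many_random_panels(self):
        """Greedy clumping equals an exhaustive reference on small panels."""
        mismatches = 0
        for seed in range(100):
            panel = blocky_panel(seed * 7 + 1, m_snps=40, n_blocks=8, n=150)
            rng = np.random.default_rng(seed)
            df = panel.variants.copy()
            df["eaf"] = 0.3
            df["beta"] = rng.normal(size=len(df))
            df["se"] = 1.0
            df["pvalue"] = rng.uniform(size=len(df))
            df["n_eff"] = 100.0
            stats = SumStats(df, "t")
            got = ld.ld_clump(stats, panel, p_threshold=0.5,
                              r2_threshold=0.2, window_kb=20)
            leads, membership = brute_force_clump(stats, panel, 0.5, 0.2, 20)
            if got.lead_snps != leads or got.membership != membership:
                mismatches += 1
        assert mismatches == 0

    def test_no_snp_below_threshold_gives_empty_result(self):
        panel = blocky_panel(3)
        df = panel.variants.copy()
        df["eaf"], df["beta"], df["se"], df["n_eff"] = 0.3, 0.0, 1.0, 100.0
        df["pvalue"] = 0.9
        result = ld.ld_clump(SumStats(df, "t"), panel, p_threshold=1e-5)
        assert len(result) == 0

    def test_tight_block_collapses_to_single_smallest_p_lead(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.5, 500).astype(float)
        noisy = np.column_stack(
            [np.where(rng.random(500) < 0.02, 2 - base, base) for _ in range(3)]
        )
        panel = toy_panel(noisy)
        df = panel.variants.copy()
        df["eaf"], df["beta"], df["se"], df["n_eff"] = 0.5, 0.0, 1.0, 100.0
        df["pvalue"] = [0.3, 0.001, 0.2]
        result = ld.ld_clump(SumStats(df, "t"), panel, p_threshold=1.0,
                             r2_threshold=0.1, window_kb=100)
        assert result.lead_snps == ["v1"]
        assert result.membership == {"v0": "v1", "v1": "v1", "v2": "v1"}

    def test_blocks_beyond_window_stay_separate_leads(self):
        rng = np.random.default_rng(5)
        base = rng.binomial(2, 0.5, 500).astype(float)
        panel = toy_panel(
            np.column_stack([base, base]), positions=[1_000, 5_000_000]
        )
        df = panel.variants.copy()
        df["eaf"], df["beta"], df["se"], df["n_eff"] = 0.5, 0.0, 1.0, 100.0
        df["pvalue"] = [0.001, 0.002]
        result = ld.ld_clump(SumStats(df, "t"), panel, p_threshold=1.0,
                             r2_threshold=0.1, window_kb=1000)
        assert len(result) == 2

    def test_leads_are_mutually_independent_within_window(self):
        panel = blocky_panel(9, m_snps=60, n_blocks=10, n=250)
        rng = np.random.default_rng(9)
        df = panel.variants.copy()
        df["eaf"], df["beta"], df["se"], df["n_eff"] = 0.3, 0.0, 1.0, 100.0
        df["pvalue"] = rng.uniform(size=len(df))
        result = ld.ld_clump(SumStats(df, "t"), panel, p_threshold=1.0,
                             r2_threshold=0.15, window_kb=30)
        for i, a in enumerate(result.lead_snps):
            for b in result.lead_snps[i + 1 :]:
                pa = panel.variants.set_index("snp_id")
                if pa.at[a, "chrom"] != pa.at[b, "chrom"]:
                    continue
                if abs(int(pa.at[a, "pos"]) - int(pa.at[b, "pos"])) > 30_000:
                    continue
                assert ld.pairwise_r2(panel, a, b) <= 0.15

    def test_snp_absent_from_panel_becomes_own_lead(self):
        panel = blocky_panel(6)
        df = panel.variants.copy()
        df["eaf"], df["beta"], df["se"], df["n_eff"] = 0.3, 0.0, 1.0, 100.0
        df["pvalue"] = 0.5
        extra = df.iloc[[0]].assign(snp_id="ghost", pvalue=1e-9, pos=123)
        stats = SumStats(pd.concat([df, extra], ignore_index=True), "t")
        result = ld.ld_clump(stats, panel, p_threshold=1e-6)
        assert result.lead_snps == ["ghost"]


class TestFindProxy:
    def test_target_in_candidates_returns_itself(self):
        panel = blocky_panel(12)
        target = panel.variants["snp_id"].iloc[0]
        assert ld.find_proxy(panel, target, {target}) == target

    def test_no_candidate_above_threshold_returns_none(self):
        rng = np.random.default_rng(13)
        panel = toy_panel(rng.binomial(2, 0.4, (2000, 3)))
        assert ld.find_proxy(panel, "v0", {"v1", "v2"}, min_r2=0.8) is None

    def test_highest_r2_candidate_wins(self):
        rng = np.random.default_rng(14)
        base = rng.binomial(2, 0.5, 3000).astype(float)

        def corrupt(rate):
            flip = rng.random(3000) < rate
            return np.where(flip, rng.binomial(2, 0.5, 3000), base)

        panel = toy_panel(np.column_stack([base, corrupt(0.03), corrupt(0.10)]))
        got = ld.find_proxy(panel, "v0", {"v1", "v2"}, min_r2=0.5)
        assert got == "v1"

    def test_proxy_of_proxy_is_idempotent(self):
        panel = blocky_panel(15, m_snps=30, n_blocks=5, n=400)
        candidates = set(panel.variants["snp_id"])
        target = panel.variants["snp_id"].iloc[2]
        proxy = ld.find_proxy(panel, target, candidates, min_r2=0.2)
        assert proxy is not None
        assert ld.find_proxy(panel, proxy, candidates, min_r2=0.2) == proxy


class TestLdPartners:
    def test_isolated_snp_partners_with_itself_only(self):
        rng = np.random.default_rng(16)
        panel = toy_panel(rng.binomial(2, 0.4, (5000, 4)))
        assert ld.ld_partners(panel, "v0", min_r2=0.3, window_kb=100) == {"v0"}

    def test_matches_brute_force_scan(self):
        panel = blocky_panel(17, m_snps=25, n_blocks=5, n=300)
        target = panel.variants["snp_id"].iloc[1]
        got = ld.ld_partners(panel, target, min_r2=0.2, window_kb=50)
        pa = panel.variants.set_index("snp_id")
        expected = {target}
        for sid in panel.variants["snp_id"]:
            if sid == target or pa.at[sid, "chrom"] != pa.at[target, "chrom"]:
                continue
            if abs(int(pa.at[sid, "pos"]) - int(pa.at[target, "pos"])) > 50_000:
                continue
            if ld.pairwise_r2(panel, target, sid) > 0.2:
                expected.add(sid)
        assert got == expected

    def test_zero_threshold_returns_whole_window(self):
        panel = blocky_panel(18, m_snps=20, n_blocks=4, n=200)
        target = panel.variants["snp_id"].iloc[0]
        got = ld.ld_partners(panel, target, min_r2=0.0, window_kb=1e6)
        chrom = panel.variants.set_index("snp_id").at[target, "chrom"]
        assert got == set(
            panel.variants.loc[panel.variants["chrom"] == chrom, "snp_id"]
        )

    def test_unknown_target_raises(self):
        panel = blocky_panel(19)
        with pytest.raises(ld.LdError):
            ld.ld_partners(panel, "nope", 0.5, 100)


class TestLdScores:
    def test_singleton_universe_scores_one(self):
        rng = np.random.default_rng(20)
        panel = toy_panel(rng.binomial(2, 0.3, (100, 3)))
        table = ld.ld_scores(panel, universe={"v1"}, window_kb=100)
        assert table.df["ld_score"].iloc[0] == pytest.approx(1.0)

    def test_independent_snps_unadjusted_inflated_adjusted_near_one(self):
        rng = np.random.default_rng(21)
        n, m = 400, 30
        panel = toy_panel(
            rng.binomial(2, 0.4, (n, m)),
            positions=np.arange(1, m + 1) * 100,  # all within one window
        )
        raw = ld.ld_scores(panel, window_kb=100, adjusted=False)
        adj = ld.ld_scores(panel, window_kb=100, adjusted=True)
        # each null pair contributes ~1/n unadjusted
        assert raw.df["ld_score"].mean() == pytest.approx(1 + (m - 1) / n, abs=0.05)
        assert adj.df["ld_score"].mean() == pytest.approx(1.0, abs=0.05)

    def test_widening_window_never_decreases_unadjusted_scores(self):
        panel = blocky_panel(22, m_snps=40, n_blocks=8, n=200)
        narrow = ld.ld_scores(panel, window_kb=5, adjusted=False)
        wide = ld.ld_scores(panel, window_kb=500, adjusted=False)
        assert np.all(
            wide.df["ld_score"].to_numpy() >= narrow.df["ld_score"].to_numpy() - 1e-9
        )

    def test_scores_at_least_one_unadjusted(self):
        panel = blocky_panel(23)
        table = ld.ld_scores(panel, window_kb=100, adjusted=False)
        assert (table.df["ld_score"] >= 1 - 1e-9).all()


class TestPanelIO:
    def test_matrix_round_trip(self, tmp_path):
        panel = blocky_panel(30, m_snps=12, n_blocks=3, n=40)
        ld.write_matrix_panel(panel, tmp_path / "m.tsv", tmp_path / "v.tsv")
        back = ld.read_matrix_panel(tmp_path / "m.tsv", tmp_path / "v.tsv")
        np.testing.assert_allclose(back.dosages, panel.dosages)
        assert list(back.variants["snp_id"]) == list(panel.variants["snp_id"])

    def test_vcf_panel_matches_hand_written_genotypes(self, tmp_path):
        vcf = tmp_path / "tiny.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trsB\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n"
        )
        panel = ld.read_vcf_panel(vcf)
        assert panel.sample_count == 3
        np.testing.assert_allclose(panel.dosages[:, 0], [0, 1, 2])
        assert panel.dosages[1, 1] != panel.dosages[1, 1]  # NaN for missing
        assert list(panel.variants["effect_allele"]) == ["G", "T"]
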