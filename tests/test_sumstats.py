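"""Summary-statistic reading, harmonization and QC filters."""

import numpy as np
import pandas as pd
import pytest

from crosstrait import sumstats as ss


class TestReadSumstats:
    def test_well_formed_file_reads_all_rows(self, sumstats_file):
        table, report = ss.read_sumstats(sumstats_file(), trait_label="t")
        assert len(table) == 5
        assert report.n_output == 5
        assert report.n_dropped == 0
        assert table.trait_label == "t"

    def test_or_one_becomes_beta_zero(self, sumstats_file):
        path = sumstats_file(beta=[1.0, 1.5, 2.0, 1.0, 0.8])
        table, _ = ss.read_sumstats(path, or_column=True)
        by_id = table.df.set_index("snp_id")["beta"]
        assert by_id["rs1"] == 0.0
        assert by_id["rs4"] == 0.0
        assert by_id["rs2"] == pytest.approx(np.log(1.5))

    def test_out_of_range_eaf_dropped_and_counted(self, sumstats_file):
        path = sumstats_file(eaf=[1.2, 0.25, 0.4, 0.3, 0.45])
        table, report = ss.read_sumstats(path)
        assert len(table) == 4
        assert report.n_dropped_by_rule["range"] == 1
        assert "rs1" not in set(table.df["snp_id"])

    def test_non_acgt_allele_dropped_under_allele_rule(self, sumstats_file):
        path = sumstats_file(effect_allele=["I", "C", "G", "T", "A"])
        _, report = ss.read_sumstats(path)
        assert report.n_dropped_by_rule["alleles"] == 1

    def test_missing_column_is_config_error(self, sumstats_file, sumstats_frame):
        path = sumstats_file(sumstats_frame.drop(columns=["se"]))
        with pytest.raises(ss.ConfigError):
            ss.read_sumstats(path)

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("snp_id\tchrom\tpos\n")
        with pytest.raises((ss.InputError, Exception)):
            ss.read_sumstats(path)

    def test_column_map_renames_physical_columns(self, tmp_path, sumstats_frame):
        df = sumstats_frame.rename(columns={"snp_id": "SNP", "pvalue": "P"})
        path = tmp_path / "renamed.tsv"
        df.to_csv(path, sep="\t", index=False)
        cmap = {c: c for c in ss.CORE_COLUMNS}
        cmap.update(snp_id="SNP", pvalue="P")
        table, _ = ss.read_sumstats(path, column_map=cmap)
        assert len(table) == 5

    def test_round_trip_preserves_ten_significant_digits(self, tmp_path, sumstats_frame):
        df = sumstats_frame.assign(beta=[0.123456789012, -1e-7, 3.3e-2, 0.5, -2.0])
        table = ss.SumStats(df, "t")
        out = tmp_path / "rt.tsv"
        ss.write_sumstats(table, out)
        back, _ = ss.read_sumstats(out)
        for col in ("beta", "se", "pvalue", "eaf"):
            np.testing.assert_allclose(
                back.df[col].to_numpy(), table.df[col].to_numpy(), rtol=1e-10
            )


class TestCoverageFilter:
    def test_zero_threshold_is_noop(self, sumstats_frame):
        table = ss.SumStats(sumstats_frame, "t")
        out, report = ss.coverage_filter(table, 0)
        assert len(out) == len(table)
        assert report.n_dropped == 0

    def test_counts_drops_by_enumeration(self, conftest_rng=None):
        rng = np.random.default_rng(5)
        n = 10
        df = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "chrom": "1",
                "pos": np.arange(1, n + 1) * 10,
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": 0.3,
                "beta": 0.0,
                "se": 1.0,
                "pvalue": 0.5,
                "n_eff": [5.0, 25.0, 30.0, 10.0, 50.0, 19.0, 21.0, 40.0, 22.0, 3.0],
            }
        )
        table = ss.SumStats(df, "t")
        out, report = ss.coverage_filter(table, min_n=19)
        expected_keep = sum(v >= 19 for v in df["n_eff"])
        assert len(out) == expected_keep == 7
        assert report.n_dropped_by_rule["coverage"] == 3
        assert report.n_output == report.n_input - report.n_dropped

    def test_all_below_threshold_gives_empty_table(self, sumstats_frame):
        table = ss.SumStats(sumstats_frame, "t")
        out, report = ss.coverage_filter(table, min_n=1e9)
        assert len(out) == 0
        assert report.n_dropped == 5


def _pair(df_a, df_b):
    return ss.SumStats(df_a, "a"), ss.SumStats(df_b, "b")


class TestAlignAndMerge:
    def test_identical_coding_leaves_betas_unchanged(self, sumstats_frame):
        a, b = _pair(sumstats_frame, sumstats_frame)
        merged, report = ss.align_and_merge(a, b)
        np.testing.assert_allclose(
            merged.df["beta_a"].to_numpy(), merged.df["beta_b"].to_numpy()
        )
        assert report.n_dropped == 0

    def test_swapped_alleles_flip_beta_and_eaf(self, sumstats_frame):
        other = sumstats_frame.copy()
        other["effect_allele"], other["other_allele"] = (
            sumstats_frame["other_allele"],
            sumstats_frame["effect_allele"],
        )
        other["beta"] = 0.3
        other["eaf"] = 0.2
        a, b = _pair(sumstats_frame, other)
        merged, _ = ss.align_and_merge(a, b)
        np.testing.assert_allclose(merged.df["beta_b"], -0.3)
        np.testing.assert_allclose(merged.df["eaf_b"], 0.8)

    def test_mismatched_allele_pair_dropped(self, sumstats_frame):
        other = sumstats_frame.copy()
        # rs1 in a is A/G; make it A/C in b -> irreconcilable
        other.loc[other["snp_id"] == "rs1", "other_allele"] = "C"
        a, b = _pair(sumstats_frame, other)
        merged, report = ss.align_and_merge(a, b)
        assert "rs1" not in set(merged.df["snp_id"])
        assert report.n_dropped_by_rule["allele_mismatch"] == 1

    def test_strand_ambiguous_dropped_only_when_flagged(self, sumstats_frame):
        df = sumstats_frame.copy()
        df.loc[df["snp_id"] == "rs2", ["effect_allele", "other_allele"]] = ["A", "T"]
        a, b = _pair(df, df)
        merged_keep, _ = ss.align_and_merge(a, b, drop_strand_ambiguous=False)
        merged_drop, report = ss.align_and_merge(a, b, drop_strand_ambiguous=True)
        assert "rs2" in set(merged_keep.df["snp_id"])
        assert "rs2" not in set(merged_drop.df["snp_id"])
        assert report.n_dropped_by_rule["strand_ambiguous"] == 1

    def test_flip_logic_symmetric_in_argument_order(self, sumstats_frame):
        other = sumstats_frame.copy()
        flip = other["snp_id"].isin(["rs1", "rs4"])
        ea, oa = other["effect_allele"].copy(), other["other_allele"].copy()
        other.loc[flip, "effect_allele"] = oa[flip]
        other.loc[flip, "other_allele"] = ea[flip]
        other.loc[flip, "beta"] = -other.loc[flip, "beta"]
        other.loc[flip, "eaf"] = 1 - other.loc[flip, "eaf"]
        a, b = _pair(sumstats_frame, other)
        m1, _ = ss.align_and_merge(a, b)
        m2, _ = ss.align_and_merge(b, a)
        assert set(m1.df["snp_id"]) == set(m2.df["snp_id"])
        s1 = m1.df.set_index("snp_id")
        s2 = m2.df.set_index("snp_id")
        np.testing.assert_allclose(
            np.abs(s1["beta_a"]), np.abs(s2["beta_b"].reindex(s1.index))
        )

    def test_zero_intersection_raises_input_error(self, sumstats_frame):
        other = sumstats_frame.copy()
        other["snp_id"] = other["snp_id"] + "_x"
        a, b = _pair(sumstats_frame, other)
        with pytest.raises(ss.InputError):
            ss.align_and_merge(a, b)


class TestMafDivergenceFilter:
    def _merged(self, eaf_a, eaf_b):
        n = len(eaf_a)
        df = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "chrom": "1",
                "pos": np.arange(1, n + 1),
                "effect_allele": "A",
                "other_allele": "G",
                "eaf_a": eaf_a,
                "beta_a": 0.0,
                "se_a": 1.0,
                "pvalue_a": 0.5,
                "n_eff_a": 100.0,
                "eaf_b": eaf_b,
                "beta_b": 0.0,
                "se_b": 1.0,
                "pvalue_b": 0.5,
                "n_eff_b": 100.0,
            }
        )
        return ss.MergedStats(df)

    def test_thousand_distinct_diffs_drop_ten_per_tail(self):
        rng = np.random.default_rng(0)
        eaf_a = rng.uniform(0.1, 0.9, 1000)
        diffs = rng.permutation(np.linspace(-0.04, 0.04, 1000))
        eaf_b = np.clip(eaf_a - diffs, 0.01, 0.99)
        merged = self._merged(eaf_a, eaf_a - diffs)
        out, report = ss.maf_divergence_filter(merged, 1, 99)
        assert report.n_dropped_by_rule["maf_divergence"] == 20
        # brute-force oracle: which SNPs sit strictly outside the cutoffs
        lo, hi = np.percentile(diffs, [1, 99])
        assert set(out.df["snp_id"]) == set(
            merged.df["snp_id"][(diffs >= lo) & (diffs <= hi)]
        )

    def test_degenerate_identical_diffs_drop_nothing(self):
        eaf = np.full(50, 0.3)
        merged = self._merged(eaf, eaf - 0.01)
        out, report = ss.maf_divergence_filter(merged)
        assert len(out) == 50
        assert report.n_dropped == 0

    def test_full_bounds_are_noop(self):
        rng = np.random.default_rng(1)
        eaf_a = rng.uniform(0.1, 0.9, 100)
        merged = self._merged(eaf_a, rng.uniform(0.1, 0.9, 100))
        out, _ = ss.maf_divergence_filter(merged, 0, 100)
        assert len(out) == 100

    def test_inverted_bounds_are_config_error(self):
        merged = self._merged(np.full(10, 0.3), np.full(10, 0.3))
        with pytest.raises(ss.ConfigError):
            ss.maf_divergence_filter(merged, 99, 1)


class TestBetaFromZ:
    def test_zero_z_gives_zero_beta(self):
        assert ss.beta_from_z(0.0, 1000, 0.3) == 0.0

    def test_closed_form_value(self):
        assert ss.beta_from_z(2.0, 10_000, 0.5) == pytest.approx(
            2.0 / np.sqrt(5000.0)
        )

    def test_maf_folding_symmetry(self):
        assert ss.beta_from_z(1.7, 5000, 0.3) == ss.beta_from_z(1.7, 5000, 0.7)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=20)
        eaf = rng.uniform(0.01, 0.49, 20)
        n = rng.uniform(1e3, 1e5, 20)
        back = ss.z_from_beta(ss.beta_from_z(z, n, eaf), n, eaf)
        np.testing.assert_allclose(back, z, rtol=1e-12)

    def test_degenerate_eaf_rejected(self):
        with pytest.raises(ValueError):
            ss.beta_from_z(1.0, 100, 1.0)
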