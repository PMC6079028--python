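"""Reading, harmonizing and quality-filtering GWAS summary statistics.

Every downstream stage (clumping, lookup, LDSC, GWIS, scoring) consumes the
:class:`SumStats` container produced here, so the QC conventions live in one
place: per-SNP coverage filtering, allele alignment between two result files
(with sign/frequency flips when the effect allele is swapped), optional
removal of strand-ambiguous (A/T, C/G) variants, and a two-tailed filter on
the distribution of allele-frequency differences between files.

Positions are 1-based and windows are inclusive on both ends throughout the
package.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
#: A/T and C/G pairs cannot be disambiguated under a strand flip.
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

CORE_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n_eff",
]


class ConfigError(ValueError):
    """Invalid user-supplied configuration (column maps, thresholds)."""


class InputError(ValueError):
    """Structurally unusable input data (empty file, zero intersection)."""


@dataclass
class CaseControlDesign:
    """Case/control sample sizes of a binary-trait GWAS."""

    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("case and control counts must be positive")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class QcReport:
    """Accounting of dropped records; each record is attributed to exactly
    one (first-failing) rule, so drops always sum to n_input - n_output."""

    n_input: int
    n_dropped_by_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return int(sum(self.n_dropped_by_rule.values()))

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_dropped

    def add(self, rule: str, count: int) -> None:
        if count:
            self.n_dropped_by_rule[rule] = (
                self.n_dropped_by_rule.get(rule, 0) + int(count)
            )

    def to_text(self) -> str:
        lines = [f"n_input\t{self.n_input}"]
        for rule, cnt in self.n_dropped_by_rule.items():
            lines.append(f"dropped.{rule}\t{cnt}")
        lines.append(f"n_output\t{self.n_output}")
        return "\n".join(lines) + "\n"


@dataclass
class SumStats:
    """Harmonized per-SNP association results for one trait.

    ``df`` carries the :data:`CORE_COLUMNS`; rows are unique on ``snp_id``
    and sorted by (chrom, pos).
    """

    df: pd.DataFrame
    trait_label: str = ""
    design: CaseControlDesign | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"summary statistics missing columns: {missing}")
        self.df = _sort_variants(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.df["snp_id"])

    def zscores(self) -> np.ndarray:
        return (self.df["beta"] / self.df["se"]).to_numpy()

    def chisq(self) -> np.ndarray:
        return self.zscores() ** 2


@dataclass
class MergedStats:
    """Two traits' results side by side on one aligned SNP universe.

    Trait-specific columns are suffixed ``_a`` / ``_b``; allele columns are
    the shared (trait-a) coding after any flips.
    """

    df: pd.DataFrame
    label_a: str = "a"
    label_b: str = "b"

    def __len__(self) -> int:
        return len(self.df)

    def trait(self, which: str) -> SumStats:
        """Extract one trait back out as a standalone :class:`SumStats`."""
        if which not in ("a", "b"):
            raise ConfigError("which must be 'a' or 'b'")
        cols = {f"{c}_{which}": c for c in ("eaf", "beta", "se", "pvalue", "n_eff")}
        out = self.df[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
        for src, dst in cols.items():
            out[dst] = self.df[src].to_numpy()
        label = self.label_a if which == "a" else self.label_b
        return SumStats(out, trait_label=label)


def _sort_variants(df: pd.DataFrame) -> pd.DataFrame:
    chrom_num = pd.to_numeric(df["chrom"], errors="coerce")
    order = np.lexsort((df["pos"].to_numpy(), chrom_num.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


DEFAULT_COLUMN_MAP = {c: c for c in CORE_COLUMNS}


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    or_column: bool = False,
    design: CaseControlDesign | None = None,
) -> tuple[SumStats, QcReport]:
    """Read delimited summary statistics, validating and dropping bad rows.

    Parameters
    ----------
    column_map
        Maps logical field names (:data:`CORE_COLUMNS`) to the physical
        header names in the file. The ``beta`` entry may point at an
        odds-ratio column when ``or_column`` is set, in which case the
        natural log is taken.
    or_column
        Interpret the effect column as an odds ratio.

    Rows failing type or range checks are dropped and counted in the
    returned :class:`QcReport` under the first failing rule.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    missing = [k for k in CORE_COLUMNS if k not in cmap]
    if missing:
        raise ConfigError(f"column_map missing entries for {missing}")

    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=None, engine="python", dtype=str)
    if raw.empty:
        raise InputError(f"no data rows in {path}")
    absent = [v for v in cmap.values() if v not in raw.columns]
    if absent:
        raise ConfigError(f"columns {absent} not present in {path}")

    df = pd.DataFrame({k: raw[v] for k, v in cmap.items()})
    report = QcReport(n_input=len(df))

    for col in ("pos",):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "pvalue", "n_eff"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].astype(str).str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()

    numeric = ["pos", "eaf", "beta", "se", "pvalue", "n_eff"]
    bad_type = df[numeric].isna().any(axis=1)
    report.add("type", bad_type.sum())
    df = df[~bad_type]

    if or_column:
        nonpos = df["beta"] <= 0
        report.add("nonpositive_or", nonpos.sum())
        df = df[~nonpos]
        df = df.assign(beta=np.log(df["beta"].to_numpy()))

    ok_alleles = (
        df["effect_allele"].isin(list(VALID_ALLELES))
        & df["other_allele"].isin(list(VALID_ALLELES))
        & (df["effect_allele"] != df["other_allele"])
    )
    report.add("alleles", (~ok_alleles).sum())
    df = df[ok_alleles]

    in_range = (
        df["eaf"].gt(0) & df["eaf"].lt(1)
        & df["se"].gt(0)
        & df["pvalue"].gt(0) & df["pvalue"].le(1)
        & df["n_eff"].gt(0)
        & df["pos"].ge(1)
    )
    report.add("range", (~in_range).sum())
    df = df[in_range]

    dup = df["snp_id"].duplicated(keep="first")
    report.add("duplicate_id", dup.sum())
    df = df[~dup]

    df = df.astype({"pos": np.int64})
    table = SumStats(df.reset_index(drop=True), trait_label=trait_label, design=design)
    return table, report


def write_sumstats(table: SumStats, path) -> None:
    """Write a harmonized table back out as tab-delimited text (full
    precision: round-trips to 10+ significant digits)."""
    out = table.df[CORE_COLUMNS]
    opener = gzip.open(str(path), "wt") if str(path).endswith(".gz") else open(path, "w")
    with opener as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def coverage_filter(table: SumStats, min_n: float) -> tuple[SumStats, QcReport]:
    """Keep records with per-SNP sample size (or any monotone surrogate such
    as a contributing-cohort count) at or above ``min_n``."""
    if min_n < 0:
        raise ConfigError("min_n must be non-negative")
    report = QcReport(n_input=len(table))
    keep = table.df["n_eff"] >= min_n
    report.add("coverage", (~keep).sum())
    return (
        SumStats(table.df[keep].reset_index(drop=True), table.trait_label, table.design),
        report,
    )


def align_and_merge(
    a: SumStats,
    b: SumStats,
    drop_strand_ambiguous: bool = False,
) -> tuple[MergedStats, QcReport]:
    """Intersect two tables on snp_id and align trait b to trait a's allele
    coding.

    Where b's effect allele equals a's other allele (and vice versa), b's
    beta sign is flipped and its frequency folded (eaf -> 1 - eaf).
    Irreconcilable allele pairs are dropped; A/T and C/G variants are dropped
    when ``drop_strand_ambiguous`` is set (they cannot be distinguished from
    strand flips).
    """
    report = QcReport(n_input=len(a))
    merged = a.df.merge(
        b.df, on="snp_id", suffixes=("_a", "_b"), how="inner"
    )
    report.add("not_in_both", len(a) - len(merged))
    if merged.empty:
        raise InputError(
            f"zero SNP intersection between {a.trait_label!r} ({len(a)} SNPs) "
            f"and {b.trait_label!r} ({len(b)} SNPs)"
        )

    ea_a = merged["effect_allele_a"]
    oa_a = merged["other_allele_a"]
    ea_b = merged["effect_allele_b"]
    oa_b = merged["other_allele_b"]

    same = (ea_a == ea_b) & (oa_a == oa_b)
    swapped = (ea_a == oa_b) & (oa_a == ea_b)
    keep = same | swapped
    report.add("allele_mismatch", (~keep).sum())
    merged = merged[keep]
    swapped = swapped[keep]

    if drop_strand_ambiguous:
        pairs = list(zip(merged["effect_allele_a"], merged["other_allele_a"]))
        ambiguous = np.array([p in AMBIGUOUS_PAIRS for p in pairs])
        report.add("strand_ambiguous", ambiguous.sum())
        merged = merged[~ambiguous]
        swapped = swapped[~ambiguous]

    flip = swapped.to_numpy()
    beta_b = merged["beta_b"].to_numpy().copy()
    eaf_b = merged["eaf_b"].to_numpy().copy()
    beta_b[flip] = -beta_b[flip]
    eaf_b[flip] = 1.0 - eaf_b[flip]

    out = pd.DataFrame(
        {
            "snp_id": merged["snp_id"].to_numpy(),
            "chrom": merged["chrom_a"].to_numpy(),
            "pos": merged["pos_a"].to_numpy(),
            "effect_allele": merged["effect_allele_a"].to_numpy(),
            "other_allele": merged["other_allele_a"].to_numpy(),
            "eaf_a": merged["eaf_a"].to_numpy(),
            "beta_a": merged["beta_a"].to_numpy(),
            "se_a": merged["se_a"].to_numpy(),
            "pvalue_a": merged["pvalue_a"].to_numpy(),
            "n_eff_a": merged["n_eff_a"].to_numpy(),
            "eaf_b": eaf_b,
            "beta_b": beta_b,
            "se_b": merged["se_b"].to_numpy(),
            "pvalue_b": merged["pvalue_b"].to_numpy(),
            "n_eff_b": merged["n_eff_b"].to_numpy(),
        }
    )
    out = _sort_variants(out)
    return MergedStats(out, a.trait_label or "a", b.trait_label or "b"), report


def maf_divergence_filter(
    merged: MergedStats, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> tuple[MergedStats, QcReport]:
    """Drop SNPs in the tails of the distribution of differences in aligned
    effect-allele frequency between the two result files.

    The signed difference ``eaf_a - eaf_b`` is computed per SNP; records
    strictly below the ``lower_pct`` percentile or strictly above the
    ``upper_pct`` percentile (linear-interpolation quantiles) are removed.
    This targets coding errors, residual strand flips and genuine frequency
    divergence between the two GWAS samples.
    """
    if lower_pct >= upper_pct:
        raise ConfigError("lower_pct must be below upper_pct")
    report = QcReport(n_input=len(merged))
    diff = merged.df["eaf_a"].to_numpy() - merged.df["eaf_b"].to_numpy()
    lo = np.percentile(diff, lower_pct)
    hi = np.percentile(diff, upper_pct)
    keep = (diff >= lo) & (diff <= hi)
    report.add("maf_divergence", (~keep).sum())
    out = merged.df[keep].reset_index(drop=True)
    return MergedStats(out, merged.label_a, merged.label_b), report


def beta_from_z(z, n, eaf):
    """Standardized-scale effect size implied by a z-statistic.

    beta = z / sqrt(n * 2 * maf * (1 - maf)), with maf the folded frequency
    min(eaf, 1 - eaf). Used to put z-only GWAS results (e.g. a meta-analysis
    releasing only z-scores) on a per-allele beta scale for scoring.
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any(n <= 0):
        raise ValueError("n must be positive")
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must lie strictly inside (0, 1)")
    maf = np.minimum(eaf, 1.0 - eaf)
    out = z / np.sqrt(n * 2.0 * maf * (1.0 - maf))
    return float(out) if out.ndim == 0 else out


def z_from_beta(beta, n, eaf):
    """Inverse of :func:`beta_from_z` at the same (n, eaf)."""
    eaf = np.asarray(eaf, dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    out = np.asarray(beta, dtype=float) * np.sqrt(
        np.asarray(n, dtype=float) * 2.0 * maf * (1.0 - maf)
    )
    return float(out) if out.ndim == 0 else out
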