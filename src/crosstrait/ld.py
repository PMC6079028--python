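"""LD computations from a genotype reference panel.

Pairwise r² (squared dosage correlation), greedy P-value-ordered clumping,
proxy search, LD-partner extraction, and LD scores all live here. The panel
is an in-memory dosage matrix (samples x variants, values 0/1/2 with NaN for
missing) plus a variant index; VCF and a plain transposed text matrix are
both accepted on disk.

Windows are measured lead-to-candidate in basepairs, inclusive at both ends;
a window of ``w`` kb means |pos_i - pos_j| <= 1000 * w. Clump windows set
absurdly large (the PLINK ``--clump-kb 1000000`` idiom) therefore behave
chromosome-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStats

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]


class LdError(ValueError):
    """Undefined LD (monomorphic variant, missing variant, too few samples)."""


@dataclass
class GenotypePanel:
    """Reference genotypes for LD estimation.

    ``dosages``: float array, samples x variants, entries in {0, 1, 2} or NaN.
    ``variants``: frame with :data:`VARIANT_COLUMNS`, aligned to columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be samples x variants")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant index does not match dosage columns")
        if self.variants["snp_id"].duplicated().any():
            raise ValueError("duplicate variant ids in panel")
        self.variants = self.variants.reset_index(drop=True)
        self._index = pd.Index(self.variants["snp_id"])
        self._std: np.ndarray | None = None

    @property
    def sample_count(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def loc(self, snp_id: str) -> int:
        try:
            return int(self._index.get_loc(snp_id))
        except KeyError:
            raise LdError(f"variant {snp_id!r} not in panel") from None

    def _standardized(self) -> np.ndarray:
        """Column-standardized dosages with missing values mean-imputed
        (fast path used by the vectorized window computations; exact when the
        panel has no missingness)."""
        if self._std is None:
            X = self.dosages
            mean = np.nanmean(X, axis=0)
            Xc = np.where(np.isnan(X), mean, X) - mean
            sd = Xc.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                self._std = np.where(sd > 0, Xc / sd, 0.0)
        return self._std


@dataclass
class ClumpResult:
    """Greedy clumping output: leads in ascending-P order plus the
    lead assignment of every clumped SNP (leads map to themselves)."""

    lead_snps: list[str]
    membership: dict[str, str]
    lead_pvalues: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lead_snps)

    def members_of(self, lead: str) -> list[str]:
        return [s for s, l in self.membership.items() if l == lead]


def pairwise_r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    """Squared sample correlation of dosages over pairwise-complete samples."""
    i, j = panel.loc(snp_a), panel.loc(snp_b)
    x = panel.dosages[:, i]
    y = panel.dosages[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise LdError(f"fewer than 3 pairwise-complete samples for {snp_a}/{snp_b}")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise LdError(f"monomorphic variant among {snp_a}/{snp_b}")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def _r2_block(panel: GenotypePanel, idx: np.ndarray, jdx: np.ndarray) -> np.ndarray:
    """r² between every idx variant and every jdx variant (vectorized;
    mean-imputed standardization)."""
    Z = panel._standardized()
    n = panel.sample_count
    C = Z[:, idx].T @ Z[:, jdx] / n
    return np.clip(C * C, 0.0, 1.0)


def ld_clump(
    sumstats: SumStats,
    panel: GenotypePanel,
    p_threshold: float,
    r2_threshold: float = 0.1,
    window_kb: float = 1000.0,
) -> ClumpResult:
    """Greedy LD clumping of association results.

    Repeatedly takes the smallest-P unassigned SNP with P < ``p_threshold``
    as a lead and assigns to it every unassigned SNP on the same chromosome
    within ``window_kb`` kilobases whose r² with the lead exceeds
    ``r2_threshold``; iterates until no unassigned SNP remains below the
    threshold. SNPs absent from the panel become their own leads (logged).
    """
    df = sumstats.df
    window_bp = window_kb * 1000.0

    order = np.argsort(df["pvalue"].to_numpy(), kind="stable")
    snp_ids = df["snp_id"].to_numpy()
    chroms = df["chrom"].to_numpy()
    positions = df["pos"].to_numpy()
    pvals = df["pvalue"].to_numpy()

    in_panel = np.array([s in panel for s in snp_ids])
    n_absent = int((~in_panel).sum())
    if n_absent:
        logger.warning(
            "%d sumstats SNPs absent from panel; treated as independent singletons",
            n_absent,
        )

    assigned = np.zeros(len(df), dtype=bool)
    leads: list[str] = []
    lead_pvalues: dict[str, float] = {}
    membership: dict[str, str] = {}

    # per-chromosome position index for window queries
    by_chrom: dict[str, np.ndarray] = {
        c: np.flatnonzero(chroms == c) for c in pd.unique(chroms)
    }

    for row in order:
        if assigned[row] or pvals[row] >= p_threshold:
            continue
        lead_id = snp_ids[row]
        assigned[row] = True
        leads.append(lead_id)
        lead_pvalues[lead_id] = float(pvals[row])
        membership[lead_id] = lead_id
        if not in_panel[row]:
            continue
        cand = by_chrom[chroms[row]]
        cand = cand[
            (~assigned[cand])
            & in_panel[cand]
            & (np.abs(positions[cand] - positions[row]) <= window_bp)
        ]
        if cand.size == 0:
            continue
        lead_col = np.array([panel.loc(lead_id)])
        cand_cols = np.array([panel.loc(s) for s in snp_ids[cand]])
        r2 = _r2_block(panel, lead_col, cand_cols)[0]
        hits = cand[r2 > r2_threshold]
        assigned[hits] = True
        for s in snp_ids[hits]:
            membership[s] = lead_id

    return ClumpResult(leads, membership, lead_pvalues)


def find_proxy(
    panel: GenotypePanel,
    target: str,
    candidates,
    min_r2: float = 0.8,
    window_kb: float = 500.0,
) -> str | None:
    """Best available proxy for ``target`` among ``candidates``.

    Returns the candidate within the window with the highest r² above
    ``min_r2``; ties broken by smaller distance, then lexicographic id.
    ``None`` when nothing qualifies.
    """
    t = panel.loc(target)
    t_chrom = panel.variants.at[t, "chrom"]
    t_pos = panel.variants.at[t, "pos"]
    window_bp = window_kb * 1000.0

    rows = []
    for snp in candidates:
        if snp not in panel:
            continue
        j = panel.loc(snp)
        if panel.variants.at[j, "chrom"] != t_chrom:
            continue
        dist = abs(int(panel.variants.at[j, "pos"]) - int(t_pos))
        if dist > window_bp:
            continue
        try:
            r2 = 1.0 if snp == target else pairwise_r2(panel, target, snp)
        except LdError:
            continue
        if r2 > min_r2:
            rows.append((-r2, dist, snp))
    if not rows:
        return None
    rows.sort()
    return rows[0][2]


def ld_partners(
    panel: GenotypePanel, target: str, min_r2: float, window_kb: float
) -> set[str]:
    """All panel SNPs within the window whose r² with ``target`` exceeds
    ``min_r2``; always includes the target itself."""
    t = panel.loc(target)
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    window_bp = window_kb * 1000.0
    near = np.flatnonzero(
        (chrom == chrom[t]) & (np.abs(pos - pos[t]) <= window_bp)
    )
    out = {target}
    near = near[near != t]
    if near.size:
        r2 = _r2_block(panel, np.array([t]), near)[0]
        out.update(panel.variants["snp_id"].to_numpy()[near[r2 > min_r2]])
    return out


@dataclass
class LdScoreTable:
    """Per-SNP LD scores: ell_i = sum of r² with universe SNPs in the window
    (self term included, so unadjusted scores are >= 1)."""

    df: pd.DataFrame  # snp_id, chrom, pos, ld_score
    window_kb: float
    adjusted: bool

    def __len__(self) -> int:
        return len(self.df)

    def scores_for(self, snp_ids) -> pd.Series:
        s = self.df.set_index("snp_id")["ld_score"]
        return s.reindex(snp_ids)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def ld_scores(
    panel: GenotypePanel,
    universe=None,
    window_kb: float = 1000.0,
    adjusted: bool = False,
    chunk: int = 512,
) -> LdScoreTable:
    """LD scores over a SNP universe (default: the whole panel).

    With ``adjusted`` each r² is replaced by the bias-adjusted
    r² - (1 - r²)/(n - 2), floored at 0, so that independent SNPs contribute
    ~0 in expectation instead of ~1/n.
    """
    if universe is None:
        cols = np.arange(panel.n_variants)
    else:
        universe = set(universe)
        cols = np.array(
            [i for i, s in enumerate(panel.variants["snp_id"]) if s in universe],
            dtype=int,
        )
    if cols.size == 0:
        raise LdError("empty LD-score universe")

    variants = panel.variants.iloc[cols].reset_index(drop=True)
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy().astype(float)
    window_bp = window_kb * 1000.0
    n = panel.sample_count
    scores = np.zeros(cols.size)

    for c in pd.unique(chrom):
        rows = np.flatnonzero(chrom == c)
        order = rows[np.argsort(pos[rows], kind="stable")]
        p = pos[order]
        for start in range(0, order.size, chunk):
            blk = order[start : start + chunk]
            pb = p[start : start + chunk]
            lo = np.searchsorted(p, pb[0] - window_bp, side="left")
            hi = np.searchsorted(p, pb[-1] + window_bp, side="right")
            win = order[lo:hi]
            r2 = _r2_block(panel, cols[blk], cols[win])
            inside = np.abs(p[lo:hi][None, :] - pb[:, None]) <= window_bp
            if adjusted:
                r2 = np.maximum(r2 - (1.0 - r2) / (n - 2), 0.0)
            scores[blk] = np.where(inside, r2, 0.0).sum(axis=1)

    out = variants[["snp_id", "chrom", "pos"]].copy()
    out["ld_score"] = scores
    return LdScoreTable(out, window_kb=window_kb, adjusted=adjusted)


# ---------------------------------------------------------------------------
# Panel I/O


def read_vcf_panel(path) -> GenotypePanel:
    """Load a VCF (GT fields) as a dosage panel; dosage counts ALT alleles,
    so effect_allele is ALT and other_allele is REF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows = []
    dosage_cols = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # multi-allelic records are out of scope
        rows.append(
            {
                "snp_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "effect_allele": rec.ALT[0],
                "other_allele": rec.REF,
            }
        )
        gt = np.asarray(rec.genotype.array(), dtype=float)[:, :2]
        gt[gt < 0] = np.nan
        dosage_cols.append(gt.sum(axis=1))
    if not rows:
        raise LdError(f"no usable biallelic records in {path}")
    return GenotypePanel(np.column_stack(dosage_cols), pd.DataFrame(rows))


def read_matrix_panel(matrix_path, variant_map_path) -> GenotypePanel:
    """Plain-text panel: samples x variants dosage matrix with a snp-id
    header row, plus a side-car variant map (snp_id, chrom, pos, alleles)."""
    mat = pd.read_csv(matrix_path, sep="\t")
    variants = pd.read_csv(variant_map_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant map missing columns {missing}")
    variants = (
        variants.set_index("snp_id")
        .reindex(mat.columns)
        .rename_axis("snp_id")
        .reset_index()
    )
    return GenotypePanel(mat.to_numpy(dtype=float), variants)


def write_matrix_panel(panel: GenotypePanel, matrix_path, variant_map_path) -> None:
    pd.DataFrame(
        panel.dosages, columns=panel.variants["snp_id"]
    ).to_csv(matrix_path, sep="\t", index=False, float_format="%g")
    panel.variants[VARIANT_COLUMNS].to_csv(variant_map_path, sep="\t", index=False)
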