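"""Genome-wide inferred statistics (GWIS): trait purging.

Given summary statistics for two genetically overlapping traits a and b, the
purged trait a_(min b) is the residual of the genetic regression
a = beta * b + e with beta = cov_g(a, b) / var_g(b), applied per SNP:
eff_e = eff_a - beta * eff_b. Standard errors come from the delta method
with beta treated as fixed, with a cross-term for correlated estimation
errors when the two GWAS share samples (the cross-trait LDSC intercept
estimates that correlation). All effects are assumed to be on a common
(z-derived standardized) scale, so var_g(b) is the LDSC slope on that same
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import CrossTraitFit, LdscFit
from .sumstats import MergedStats, SumStats

logger = logging.getLogger(__name__)


def projection_beta(cross: CrossTraitFit, fit_b: LdscFit) -> float:
    """Genetic projection coefficient beta = cov_g(a, b) / var_g(b)."""
    if fit_b.h2 <= 0:
        raise ValueError("var_g of the purged-against trait must be positive")
    return cross.cov_g / fit_b.h2


def overlap_rho_from_intercept(cross: CrossTraitFit) -> float:
    """Per-SNP estimation-error correlation implied by the cross-trait LDSC
    intercept (non-zero only when the two GWAS share phenotypically
    correlated samples); clamped to [-1, 1]."""
    rho = cross.cross_intercept
    if abs(rho) > 1:
        logger.warning("cross intercept %.3f outside [-1, 1]; clamped", rho)
        rho = float(np.clip(rho, -1.0, 1.0))
    return float(rho)


@dataclass
class GwisResult:
    """Purged per-SNP statistics for trait a minus beta * trait b."""

    beta_proj: float
    overlap_rho: float
    table: pd.DataFrame  # snp_id, chrom, pos, alleles, effect_e, se_e, z_e, pvalue_e

    def to_sumstats(self, trait_label: str = "") -> SumStats:
        """Re-express the purged results as a standard summary-stat table so
        every downstream stage (clumping, LDSC, scoring) can consume them."""
        df = self.table.rename(
            columns={"effect_e": "beta", "se_e": "se", "pvalue_e": "pvalue"}
        )[
            ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
             "eaf", "beta", "se", "pvalue", "n_eff"]
        ].copy()
        return SumStats(df, trait_label=trait_label)


def purge_effects(
    merged: MergedStats,
    beta_proj: float,
    overlap_rho: float = 0.0,
    beta_var: float = 0.0,
) -> GwisResult:
    """Purge trait a's effects of their genetic overlap with trait b.

    Per SNP: effect_e = beta_a - beta_proj * beta_b and
    se_e² = se_a² + beta² se_b² - 2 beta rho se_a se_b
    (+ beta_b² var(beta) when a jackknifed beta variance is supplied).
    The merged table must be allele-aligned with strand-ambiguous SNPs
    already removed.
    """
    df = merged.df
    ba = df["beta_a"].to_numpy()
    bb = df["beta_b"].to_numpy()
    sa = df["se_a"].to_numpy()
    sb = df["se_b"].to_numpy()

    effect = ba - beta_proj * bb
    var = (
        sa**2
        + beta_proj**2 * sb**2
        - 2.0 * beta_proj * overlap_rho * sa * sb
        + beta_var * bb**2
    )
    if np.any(var <= 0):
        bad = df["snp_id"].to_numpy()[var <= 0]
        raise ValueError(
            f"non-positive purged variance at {bad[0]!r} "
            f"({bad.size} SNPs); overlap_rho={overlap_rho:g} too extreme"
        )
    se = np.sqrt(var)
    z = effect / se
    pval = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {
            "snp_id": df["snp_id"].to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "effect_allele": df["effect_allele"].to_numpy(),
            "other_allele": df["other_allele"].to_numpy(),
            "eaf": df["eaf_a"].to_numpy(),
            "n_eff": df["n_eff_a"].to_numpy(),
            "effect_e": effect,
            "se_e": se,
            "z_e": z,
            "pvalue_e": np.minimum(pval, 1.0),
        }
    )
    return GwisResult(beta_proj=beta_proj, overlap_rho=overlap_rho, table=table)
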