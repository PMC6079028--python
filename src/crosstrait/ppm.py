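"""Proxy-phenotype method (PPM): two-stage cross-trait lookup with
enrichment statistics.

Stage one clumps the proxy trait's GWAS down to approximately independent
lead SNPs below a preregistered P threshold; stage two looks those leads up
in an independent target-trait GWAS, applying a Bonferroni correction that
counts only the selected leads. Enrichment of the lookup is quantified three
ways: a sign-concordance binomial test, a raw enrichment factor against the
expectation under independent uniform tagging, and a Mann-Whitney rank test
of the leads' target P values against MAF-matched random draws. A Fisher
exact proportions test compares novel-discovery rates between EA-informed
and uninformed SNP sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld import ClumpResult, GenotypePanel, ld_clump
from .sumstats import SumStats

logger = logging.getLogger(__name__)


def select_leads(
    proxy_stats: SumStats,
    panel: GenotypePanel,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.1,
    window_kb: float = 1000.0,
) -> ClumpResult:
    """Stage one: greedy clumping of the proxy trait at the preregistered
    threshold; returns leads in ascending proxy-P order."""
    return ld_clump(
        proxy_stats,
        panel,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
    )


def second_stage_lookup(
    leads: ClumpResult, target_stats: SumStats, alpha: float = 0.05
) -> pd.DataFrame:
    """Stage two: look up each lead in the target trait.

    The Bonferroni threshold is ``alpha`` divided by the number of selected
    leads (the preregistered denominator; leads missing from the target file
    stay in the denominator and are reported with ``missing = True``).
    """
    n_leads = len(leads.lead_snps)
    if n_leads == 0:
        return pd.DataFrame(
            columns=["snp_id", "pvalue_proxy", "beta_target", "pvalue_target",
                     "missing", "nominal", "bonferroni"]
        )
    bonf = alpha / n_leads
    tdf = target_stats.df.set_index("snp_id")
    rows = []
    for snp in leads.lead_snps:
        if snp in tdf.index:
            beta = float(tdf.at[snp, "beta"])
            pval = float(tdf.at[snp, "pvalue"])
            rows.append(
                {
                    "snp_id": snp,
                    "pvalue_proxy": leads.lead_pvalues.get(snp, np.nan),
                    "beta_target": beta,
                    "pvalue_target": pval,
                    "missing": False,
                    "nominal": pval < alpha,
                    "bonferroni": pval < bonf,
                }
            )
        else:
            rows.append(
                {
                    "snp_id": snp,
                    "pvalue_proxy": leads.lead_pvalues.get(snp, np.nan),
                    "beta_target": np.nan,
                    "pvalue_target": np.nan,
                    "missing": True,
                    "nominal": False,
                    "bonferroni": False,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["bonferroni_threshold"] = bonf
    return out


def binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial P by doubling the smaller tail, capped at 1."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def sign_concordance_test(
    proxy_beta, target_beta
) -> tuple[int, int, float, float]:
    """Count leads whose proxy and target effects share sign, and test the
    share against 50% with an exact two-sided binomial test.

    Exactly-zero effects carry no sign information and are excluded (logged).
    Returns (k, n, share, pvalue).
    """
    a = np.asarray(proxy_beta, dtype=float)
    b = np.asarray(target_beta, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    zero = ok & ((a == 0) | (b == 0))
    if zero.any():
        logger.info("excluding %d zero-beta SNPs from the sign test", zero.sum())
    use = ok & ~zero
    n = int(use.sum())
    if n < 1:
        raise ValueError("no usable SNP pairs for sign test")
    k = int((np.sign(a[use]) == np.sign(b[use])).sum())
    return k, n, k / n, binomial_two_sided(k, n, 0.5)


@dataclass
class EnrichmentCounts:
    """Raw (LD-unaware) enrichment of the two-stage lookup.

    Under the null that lead status on the two traits hits independently at
    rates tau_proxy and tau_target across ``n_total_leads`` independent loci,
    the expected joint count is n_total * tau_proxy * tau_target; the factor
    is observed / expected.
    """

    n_total_leads: int
    tau_proxy: float
    tau_target: float
    n_observed: int
    expected: float
    factor: float | None

    @property
    def factor_defined(self) -> bool:
        return self.factor is not None


def raw_enrichment(
    n_total_leads: int,
    n_proxy_leads: int,
    n_target_leads: int,
    n_observed: int,
) -> EnrichmentCounts:
    """Expected joint-lead count and raw enrichment factor from the four
    clump counts (all-lead universe, proxy hits, target hits, joint hits)."""
    if n_total_leads <= 0:
        raise ValueError("n_total_leads must be positive")
    if min(n_proxy_leads, n_target_leads, n_observed) < 0:
        raise ValueError("counts must be non-negative")
    tau_p = n_proxy_leads / n_total_leads
    tau_t = n_target_leads / n_total_leads
    expected = n_total_leads * tau_p * tau_t
    if expected == 0:
        if n_observed > 0:
            logger.warning("observed joint hits with zero expectation; factor undefined")
        factor = None
    else:
        factor = n_observed / expected
    return EnrichmentCounts(
        n_total_leads=int(n_total_leads),
        tau_proxy=tau_p,
        tau_target=tau_t,
        n_observed=int(n_observed),
        expected=expected,
        factor=factor,
    )


@dataclass
class MatchedNullDraw:
    """MAF-matched null SNP draw: ``matches[lead]`` lists k pool SNPs whose
    folded target-trait frequency lies within ``maf_tolerance`` of the
    lead's; no SNP is reused anywhere in the draw."""

    matches: dict[str, list[str]]
    maf_tolerance: float
    seed: int

    def all_matched(self) -> list[str]:
        return [s for v in self.matches.values() for s in v]


def draw_matched_null(
    leads,
    pool: SumStats,
    k_per_lead: int = 10,
    maf_tolerance: float = 0.01,
    seed: int = 0,
    lead_stats: SumStats | None = None,
    on_shortfall: str = "error",
) -> MatchedNullDraw:
    """Sample k MAF-matched SNPs per lead, without replacement globally.

    ``pool`` must already exclude the leads and be approximately independent
    (pre-clumped). MAF is the folded frequency min(eaf, 1-eaf) of the pool
    (target-trait) file. Leads are processed in order of how scarce their
    eligible pool is, so an unlucky processing order cannot manufacture a
    spurious shortfall.
    """
    rng = np.random.default_rng(seed)
    lead_ids = list(leads)
    lead_set = set(lead_ids)
    pool_df = pool.df[~pool.df["snp_id"].isin(lead_set)]
    pool_ids = pool_df["snp_id"].to_numpy()
    pool_maf = np.minimum(pool_df["eaf"].to_numpy(), 1 - pool_df["eaf"].to_numpy())

    lead_maf = {}
    freq_source = (lead_stats or pool).df.set_index("snp_id")
    for lead in lead_ids:
        if lead not in freq_source.index:
            raise ValueError(f"lead {lead!r} has no frequency available for matching")
        eaf = float(freq_source.at[lead, "eaf"])
        lead_maf[lead] = min(eaf, 1 - eaf)

    eligible = {
        lead: np.flatnonzero(np.abs(pool_maf - lead_maf[lead]) <= maf_tolerance)
        for lead in lead_ids
    }
    taken = np.zeros(len(pool_ids), dtype=bool)
    matches: dict[str, list[str]] = {}
    for lead in sorted(lead_ids, key=lambda s: eligible[s].size):
        avail = eligible[lead][~taken[eligible[lead]]]
        if avail.size < k_per_lead:
            if on_shortfall != "truncate":
                raise ValueError(
                    f"lead {lead!r}: only {avail.size} eligible matched SNPs "
                    f"remain, need {k_per_lead}"
                )
            logger.warning(
                "lead %s: matched-null draw truncated to %d of %d",
                lead, avail.size, k_per_lead,
            )
        chosen = rng.choice(avail, size=min(k_per_lead, avail.size), replace=False)
        taken[chosen] = True
        matches[lead] = [str(s) for s in pool_ids[chosen]]
    # restore the input lead order
    matches = {lead: matches[lead] for lead in lead_ids}
    return MatchedNullDraw(matches, maf_tolerance, seed)


def mannwhitney_enrichment(lead_pvalues, null_pvalues) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test comparing the leads' target-trait
    P values with those of the matched null SNPs.

    Normal approximation with tie correction; returns (z, pvalue). A negative
    z means the leads rank lower (smaller P values) than the null draw.
    """
    x = np.asarray(lead_pvalues, dtype=float)
    y = np.asarray(null_pvalues, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both P-value lists must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 0.0, 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def novelty_proportions_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Fisher's exact test (two-sided, minimum-likelihood convention) that
    the novel-hit proportions k1/n1 and k2/n2 are equal."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
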