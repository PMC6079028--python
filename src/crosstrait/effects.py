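"""Per-SNP effect-size post-processing for case-control lookups.

Loci that reach a selection threshold carry upward-biased effect estimates
(the winner's curse); this module provides a conditional-MLE correction on
the truncated normal, two-sided power at the selection threshold, log-OR
standard errors from a case/control design, the Cohen's-d conversion of an
odds ratio to variance explained (R²), a heuristic Bayesian posterior
probability of true association, and the equal-effects lower bound on the
number of causal loci implied by a heritability estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sumstats import CaseControlDesign

DEFAULT_PRIORS = (0.001, 0.01, 0.05, 0.10)


def selection_z(alpha: float) -> float:
    """Two-sided selection threshold on |z| implied by level ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.norm.isf(alpha / 2.0))


def power_two_sided(beta: float, se: float, alpha: float) -> float:
    """Probability that a two-sided level-``alpha`` test detects a true
    effect ``beta`` estimated with standard error ``se``:
    Phi(-c + beta/se) + Phi(-c - beta/se), c the alpha/2 normal quantile."""
    if se <= 0:
        raise ValueError("se must be positive")
    c = selection_z(alpha)
    ncp = beta / se
    return float(stats.norm.cdf(-c + ncp) + stats.norm.cdf(-c - ncp))


def winners_curse_correct(
    beta_hat: float, se: float, alpha: float, method: str = "cmle"
) -> float:
    """Winner's-curse-corrected effect estimate given selection at ``alpha``.

    ``cmle`` (default): the conditional maximum-likelihood estimate — the
    beta maximizing the Normal(beta, se²) density of the observed estimate
    truncated to the selection region {|x|/se >= z(alpha/2)}, solved
    numerically on [0, |beta_hat|] (sign symmetric).

    ``mean_inversion``: inverts the conditional-mean function
    E[beta_hat | selected, beta] instead; provided for sensitivity analysis.

    The corrected estimate keeps the observed sign and never exceeds the
    observed magnitude.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    c = selection_z(alpha)
    z_obs = abs(beta_hat) / se
    if z_obs < c - 1e-9:
        raise ValueError(
            f"estimate not significant at alpha={alpha:g} (|z|={z_obs:.3f} < {c:.3f})"
        )
    sign = 1.0 if beta_hat >= 0 else -1.0
    b = abs(beta_hat)

    if method == "cmle":
        def negloglik(beta: float) -> float:
            # density of the observed estimate under truncation to selection
            logf = stats.norm.logpdf(b, loc=beta, scale=se)
            logsel = np.log(
                stats.norm.cdf(-c + beta / se) + stats.norm.cdf(-c - beta / se)
            )
            return -(logf - logsel)

        res = optimize.minimize_scalar(
            negloglik, bounds=(0.0, b), method="bounded",
            options={"xatol": 1e-12 * max(se, 1.0)},
        )
        corrected = float(res.x)
    elif method == "mean_inversion":
        def cond_mean(beta: float) -> float:
            # E[beta_hat | |beta_hat| > c*se] for true value beta
            lo = (c * se - beta) / se
            hi = (-c * se - beta) / se
            p_hi = stats.norm.sf(lo)
            p_lo = stats.norm.cdf(hi)
            num = (
                beta * (p_hi + p_lo)
                + se * stats.norm.pdf(lo)
                - se * stats.norm.pdf(hi)
            )
            return num / (p_hi + p_lo)

        if cond_mean(0.0) >= b:
            corrected = 0.0
        else:
            corrected = float(optimize.brentq(lambda m: cond_mean(m) - b, 0.0, b))
    else:
        raise ValueError(f"unknown method {method!r}")

    return sign * min(corrected, b)


def logor_se(design: CaseControlDesign, eaf: float) -> float:
    """Approximate standard error of a per-allele log odds ratio under the
    given case/control design:
    sqrt( 1/(2*maf*(1-maf)) * (1/n_cases + 1/n_controls) )."""
    if not 0 < eaf < 1:
        raise ValueError("eaf must lie strictly inside (0, 1)")
    maf = min(eaf, 1.0 - eaf)
    return float(
        np.sqrt(
            (1.0 / (2.0 * maf * (1.0 - maf)))
            * (1.0 / design.n_cases + 1.0 / design.n_controls)
        )
    )


def or_to_r2(or_value: float, eaf: float) -> float:
    """Variance explained (fraction) implied by an odds ratio.

    Cohen's d = ln(OR) * sqrt(3) / pi; the MAF correction factor is
    a = (n1 + n2)² / (n1 n2) = 1 / (maf (1 - maf)) with n1 = N*maf,
    n2 = N*(1 - maf); R² = d² / (d² + a).
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0 < eaf < 1:
        raise ValueError("eaf must lie strictly inside (0, 1)")
    maf = min(eaf, 1.0 - eaf)
    d = np.log(or_value) * np.sqrt(3.0) / np.pi
    a = 1.0 / (maf * (1.0 - maf))
    return float(d * d / (d * d + a))


def bayesian_posterior(power: float, alpha: float, prior: float) -> float:
    """Posterior probability that a selected association is true:
    (power * pi) / (power * pi + alpha * (1 - pi))."""
    for name, v in (("power", power), ("alpha", alpha), ("prior", prior)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return power * prior / (power * prior + alpha * (1.0 - prior))


def implied_causal_count(h2: float, r2_max: float) -> float:
    """Equal-effects lower bound on the number of truly causal loci: the
    trait's SNP heritability divided by the largest per-locus R²."""
    if not 0 < r2_max <= h2 <= 1:
        raise ValueError("need 0 < r2_max <= h2 <= 1")
    return h2 / r2_max


@dataclass
class CredibilityRecord:
    """Winner's-curse-corrected effect, power, R² and the posterior grid for
    one selected SNP."""

    snp_id: str
    observed_beta: float
    se: float
    alpha: float
    corrected_beta: float
    corrected_or: float
    power: float
    r2_pct: float
    posteriors: dict[float, float]


def credibility_table(
    lookup: pd.DataFrame,
    design: CaseControlDesign,
    alpha: float,
    priors=DEFAULT_PRIORS,
    eaf_column: str = "eaf",
    beta_column: str = "beta_target",
    se_column: str | None = None,
    power_column: str | None = None,
) -> pd.DataFrame:
    """Build a credibility report for Bonferroni-surviving lookup SNPs.

    Standard errors are taken from ``se_column`` when present, otherwise
    reconstructed from (design, eaf) via :func:`logor_se`. If
    ``power_column`` is given, power is treated as an input (e.g. published
    values) rather than recomputed from the reconstructed se.
    """
    rows = []
    for _, rec in lookup.iterrows():
        beta = float(rec[beta_column])
        eaf = float(rec[eaf_column])
        se = float(rec[se_column]) if se_column else logor_se(design, eaf)
        corrected = winners_curse_correct(beta, se, alpha)
        power = (
            float(rec[power_column])
            if power_column
            else power_two_sided(corrected, se, alpha)
        )
        cor_or = float(np.exp(corrected))
        posteriors = {pi: bayesian_posterior(power, alpha, pi) for pi in priors}
        row = {
            "snp_id": rec["snp_id"],
            "observed_beta": beta,
            "se": se,
            "corrected_beta": corrected,
            "corrected_or": cor_or,
            "power": power,
            "r2_pct": 100.0 * or_to_r2(cor_or, eaf),
        }
        for pi, post in posteriors.items():
            row[f"posterior_{100 * pi:g}pct"] = post
        rows.append(row)
    return pd.DataFrame(rows)
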