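"""Minimal LD-score regression.

Fits the polygenic model E[chi²_i] = N h² ell_i / M + (1 + Na) by weighted
least squares on (chi², LD score) pairs, and its cross-trait analogue
E[z_a z_b] = sqrt(N_a N_b) cov_g ell / M + intercept, where the cross
intercept absorbs phenotypic correlation in overlapping samples. This is a
deliberately small implementation — two weight iterations, optional
block-jackknife standard errors, no chi² capping by default — adequate for
calibration on synthetic data; parity with the published reference
implementation is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ld import LdScoreTable
from .sumstats import SumStats


class FitError(RuntimeError):
    """Degenerate regression design (constant LD scores, too few SNPs)."""


@dataclass
class LdscFit:
    """Single-trait fit: SNP heritability, intercept (1 + Na), and the
    inputs that scale the model."""

    h2: float
    intercept: float
    m_snps: int
    n_mean: float
    h2_se: float | None = None
    intercept_se: float | None = None


@dataclass
class CrossTraitFit:
    """Cross-trait fit: genetic covariance on the analysis scale, the
    sample-overlap intercept, and the derived genetic correlation (undefined
    when either h² is non-positive)."""

    cov_g: float
    cross_intercept: float
    rg: float | None
    cov_g_se: float | None = None


def _weighted_ls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on (1, x); returns (slope, intercept)."""
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
    return float(coef[1]), float(coef[0])


def _jackknife(x, y, w, n_blocks):
    """Leave-one-block-out standard errors for (slope, intercept)."""
    m = x.size
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    slopes, intercepts = [], []
    for b in range(n_blocks):
        keep = np.ones(m, dtype=bool)
        keep[edges[b]:edges[b + 1]] = False
        s, i = _weighted_ls(x[keep], y[keep], w[keep])
        slopes.append(s)
        intercepts.append(i)
    fac = (n_blocks - 1) / n_blocks
    return (
        float(np.sqrt(fac * np.sum((slopes - np.mean(slopes)) ** 2))),
        float(np.sqrt(fac * np.sum((intercepts - np.mean(intercepts)) ** 2))),
    )


def _prepare(stats_tbl: SumStats, ld: LdScoreTable):
    scores = ld.scores_for(stats_tbl.df["snp_id"]).to_numpy()
    ok = np.isfinite(scores)
    return stats_tbl.df[ok].reset_index(drop=True), scores[ok]


def fit_h2(
    stats_tbl: SumStats,
    ld: LdScoreTable,
    m: int | None = None,
    max_chisq: float | None = None,
    n_jackknife_blocks: int = 0,
    min_snps: int = 50,
) -> LdscFit:
    """Fit SNP heritability and intercept from one trait's chi² statistics.

    Regression of chi²_i on N ell_i / M; weights 1 / (2 E[chi²_i]²), with
    E[chi²] from the previous pass, iterated twice. ``m`` defaults to the
    size of the LD-score universe.
    """
    df, scores = _prepare(stats_tbl, ld)
    if len(df) < min_snps:
        raise FitError(f"need at least {min_snps} SNPs with LD scores, got {len(df)}")
    m_snps = int(m if m is not None else len(ld))
    chisq = (df["beta"] / df["se"]).to_numpy() ** 2
    n = df["n_eff"].to_numpy().astype(float)
    if max_chisq is not None:
        keep = chisq <= max_chisq
        chisq, n, scores = chisq[keep], n[keep], scores[keep]
    x = n * scores / m_snps
    if np.ptp(x) <= 0:
        raise FitError("constant LD-score design; heritability not identified")

    w = np.ones_like(x)
    slope = intercept = 0.0
    for _ in range(2):
        slope, intercept = _weighted_ls(x, chisq, w)
        expected = np.maximum(slope * x + intercept, 0.1)
        w = 1.0 / (2.0 * expected**2)
    slope, intercept = _weighted_ls(x, chisq, w)

    h2_se = int_se = None
    if n_jackknife_blocks:
        h2_se, int_se = _jackknife(x, chisq, w, n_jackknife_blocks)
    return LdscFit(
        h2=slope,
        intercept=intercept,
        m_snps=m_snps,
        n_mean=float(n.mean()),
        h2_se=h2_se,
        intercept_se=int_se,
    )


def fit_cross(
    stats_a: SumStats,
    stats_b: SumStats,
    ld: LdScoreTable,
    m: int | None = None,
    fit_a: LdscFit | None = None,
    fit_b: LdscFit | None = None,
    n_jackknife_blocks: int = 0,
    min_snps: int = 50,
) -> CrossTraitFit:
    """Fit genetic covariance and the sample-overlap intercept from aligned
    z-score products: regression of z_a z_b on sqrt(N_a N_b) ell / M.

    When per-trait fits are supplied, the genetic correlation
    rg = cov_g / sqrt(h2_a h2_b) is attached (undefined-flagged if either
    h² <= 0).
    """
    merged = stats_a.df.merge(
        stats_b.df, on="snp_id", suffixes=("_a", "_b"), how="inner"
    )
    if len(merged) < min_snps:
        raise FitError(f"only {len(merged)} aligned SNPs; need {min_snps}")
    scores = ld.scores_for(merged["snp_id"]).to_numpy()
    ok = np.isfinite(scores)
    merged, scores = merged[ok], scores[ok]
    m_snps = int(m if m is not None else len(ld))

    za = (merged["beta_a"] / merged["se_a"]).to_numpy()
    zb = (merged["beta_b"] / merged["se_b"]).to_numpy()
    na = merged["n_eff_a"].to_numpy().astype(float)
    nb = merged["n_eff_b"].to_numpy().astype(float)
    y = za * zb
    x = np.sqrt(na * nb) * scores / m_snps
    if np.ptp(x) <= 0:
        raise FitError("constant LD-score design; covariance not identified")

    # var(z_a z_b) ~ E[chi2_a] E[chi2_b] + E[z_a z_b]^2 under bivariate
    # normality; per-SNP expectations come from the per-trait fits when
    # available, otherwise the mean chi2 stands in
    if fit_a is not None:
        ea = np.maximum(fit_a.h2 * na * scores / m_snps + fit_a.intercept, 0.1)
    else:
        ea = np.full_like(x, max((za**2).mean(), 0.5))
    if fit_b is not None:
        eb = np.maximum(fit_b.h2 * nb * scores / m_snps + fit_b.intercept, 0.1)
    else:
        eb = np.full_like(x, max((zb**2).mean(), 0.5))

    w = np.ones_like(x)
    slope = intercept = 0.0
    for _ in range(2):
        slope, intercept = _weighted_ls(x, y, w)
        pred = slope * x + intercept
        w = 1.0 / np.maximum(ea * eb + pred**2, 0.1)
    slope, intercept = _weighted_ls(x, y, w)

    rg = None
    if fit_a is not None and fit_b is not None:
        if fit_a.h2 > 0 and fit_b.h2 > 0:
            rg = slope / np.sqrt(fit_a.h2 * fit_b.h2)
    cov_se = None
    if n_jackknife_blocks:
        cov_se, _ = _jackknife(x, y, w, n_jackknife_blocks)
    return CrossTraitFit(
        cov_g=slope, cross_intercept=intercept, rg=rg, cov_g_se=cov_se
    )
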