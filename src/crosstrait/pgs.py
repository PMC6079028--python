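"""Polygenic-score construction and the split-score heterogeneity test.

A parent score (one weight per LD clump, log-OR weights for case-control
source GWAS) is split into *Concordant* and *Discordant* sub-scores by
whether each SNP's effect signs on the source and a second trait agree. If
the phenotype being predicted loads differently on the two components, a
regression that frees their coefficients (split model) beats one that
constrains them equal (baseline, which carries the parent score) — a nested
F-test with one numerator degree of freedom. A permutation control splits
the parent at random, preserving the split sizes, to show the sign-based
split is not an artifact of splitting per se.

Under the sum convention the parent score is exactly the sum of its two
sub-scores per individual, which makes the baseline model exactly nested in
the split model even after per-score standardization (standardizing is an
affine map, so the model spans are unchanged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ld import GenotypePanel, ld_clump
from .sumstats import SumStats

logger = logging.getLogger(__name__)


@dataclass
class ScoreDefinition:
    """A named SNP weight set: ``weights`` has columns snp_id,
    effect_allele, weight."""

    name: str
    weights: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"snp_id", "effect_allele", "weight"}
        if not need <= set(self.weights.columns):
            raise ValueError(f"score weights need columns {sorted(need)}")
        if not np.all(np.isfinite(self.weights["weight"])):
            raise ValueError("non-finite score weights")
        self.weights = self.weights.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def snp_ids(self) -> set[str]:
        return set(self.weights["snp_id"])


@dataclass
class CohortData:
    """Individual-level target cohort: genotypes plus a phenotype/covariate
    frame aligned on individual id (frame index)."""

    genotypes: GenotypePanel
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.phenotypes) != self.genotypes.sample_count:
            raise ValueError("phenotype rows must match genotype samples")


def build_score(
    stats_tbl: SumStats,
    panel: GenotypePanel,
    p_threshold: float = 1.0,
    maf_floor: float = 0.0,
    r2_threshold: float = 0.1,
    window_kb: float = 1000.0,
    name: str = "score",
) -> ScoreDefinition:
    """MAF-filter, clump, then take one weight (the source beta; log-OR for
    case-control sources) per lead SNP."""
    df = stats_tbl.df
    if maf_floor > 0:
        maf = np.minimum(df["eaf"], 1 - df["eaf"])
        df = df[maf > maf_floor]
    filtered = SumStats(df.reset_index(drop=True), stats_tbl.trait_label)
    clumps = ld_clump(
        filtered, panel, p_threshold=p_threshold,
        r2_threshold=r2_threshold, window_kb=window_kb,
    )
    leads = filtered.df.set_index("snp_id").loc[clumps.lead_snps]
    if leads.empty:
        raise ValueError("score is empty after filtering and clumping")
    weights = pd.DataFrame(
        {
            "snp_id": leads.index.to_numpy(),
            "effect_allele": leads["effect_allele"].to_numpy(),
            "weight": leads["beta"].to_numpy(),
        }
    )
    return ScoreDefinition(
        name=name,
        weights=weights,
        provenance={
            "source_trait": stats_tbl.trait_label,
            "p_threshold": p_threshold,
            "maf_floor": maf_floor,
            "r2_threshold": r2_threshold,
            "window_kb": window_kb,
        },
    )


def split_by_concordance(
    score: ScoreDefinition,
    other: SumStats,
    strategy: str = "prune_then_split",
    panel: GenotypePanel | None = None,
    full_stats: SumStats | None = None,
    r2_threshold: float = 0.1,
    window_kb: float = 1000.0,
) -> tuple[ScoreDefinition, ScoreDefinition]:
    """Split a score by sign agreement with a second trait's effects.

    ``prune_then_split`` partitions the already-clumped parent set (so LD is
    pruned both within and across the two sub-scores and their union is
    exactly the parent). ``split_then_prune`` partitions the full harmonized
    SNP set (``full_stats``) by sign first and clumps within each partition,
    yielding larger sub-scores that are LD-pruned only within themselves.
    SNPs with no sign available in ``other`` are excluded (counted in
    provenance).
    """
    signs = other.df.set_index("snp_id")["beta"]

    if strategy == "prune_then_split":
        w = score.weights
        avail = w["snp_id"].isin(signs.index)
        n_missing = int((~avail).sum())
        if n_missing:
            logger.info("%d parent SNPs lack a sign in %r; excluded",
                        n_missing, other.trait_label)
        w = w[avail]
        s_other = np.sign(signs.loc[w["snp_id"]].to_numpy())
        s_source = np.sign(w["weight"].to_numpy())
        concordant = (s_source == s_other) & (s_source != 0)
        parts = (w[concordant], w[~concordant])
    elif strategy == "split_then_prune":
        if full_stats is None or panel is None:
            raise ValueError("split_then_prune needs full_stats and a panel")
        df = full_stats.df
        avail = df["snp_id"].isin(signs.index)
        n_missing = int((~avail).sum())
        df = df[avail]
        s_other = np.sign(signs.loc[df["snp_id"]].to_numpy())
        s_source = np.sign(df["beta"].to_numpy())
        concordant = (s_source == s_other) & (s_source != 0)
        parts = []
        p_threshold = score.provenance.get("p_threshold", 1.0)
        for mask in (concordant, ~concordant):
            sub = SumStats(df[mask].reset_index(drop=True), full_stats.trait_label)
            clumps = ld_clump(sub, panel, p_threshold=p_threshold,
                              r2_threshold=r2_threshold, window_kb=window_kb)
            leads = sub.df.set_index("snp_id").loc[clumps.lead_snps]
            parts.append(
                pd.DataFrame(
                    {
                        "snp_id": leads.index.to_numpy(),
                        "effect_allele": leads["effect_allele"].to_numpy(),
                        "weight": leads["beta"].to_numpy(),
                    }
                )
            )
        parts = tuple(parts)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    prov = dict(score.provenance)
    prov.update({"split_rule": strategy, "other_trait": other.trait_label,
                 "n_sign_missing": n_missing})
    conc = ScoreDefinition(f"{score.name}_concordant", parts[0].reset_index(drop=True), prov)
    disc = ScoreDefinition(f"{score.name}_discordant", parts[1].reset_index(drop=True), prov)
    return conc, disc


def compute_scores(
    defs,
    cohort: CohortData,
    convention: str = "sum",
) -> pd.DataFrame:
    """Per-individual score values for each definition.

    ``sum``: sum of weight * dosage (missing dosages contribute 0).
    ``average_per_allele``: the sum divided by 2 x the individual's
    non-missing SNP count. Weights coded on the cohort's other allele are
    sign-flipped first.
    """
    if convention not in ("sum", "average_per_allele"):
        raise ValueError(f"unknown convention {convention!r}")
    panel = cohort.genotypes
    variants = panel.variants.set_index("snp_id")
    out = {}
    for sdef in defs:
        w = sdef.weights
        present = w["snp_id"].isin(variants.index)
        if not present.any():
            raise ValueError(f"score {sdef.name!r} shares no SNPs with the cohort")
        w = w[present]
        cols = np.array([panel.loc(s) for s in w["snp_id"]])
        coded = variants.loc[w["snp_id"]]
        flip = (coded["effect_allele"].to_numpy() != w["effect_allele"].to_numpy())
        other_match = (coded["other_allele"].to_numpy() == w["effect_allele"].to_numpy())
        if np.any(flip & ~other_match):
            bad = w["snp_id"].to_numpy()[flip & ~other_match]
            raise ValueError(f"allele mismatch between score and cohort at {bad[:5]}")
        weight = np.where(flip, -w["weight"].to_numpy(), w["weight"].to_numpy())
        offset = np.where(flip, 2.0 * w["weight"].to_numpy(), 0.0)

        G = panel.dosages[:, cols]
        miss = np.isnan(G)
        Gz = np.where(miss, 0.0, G)
        vals = Gz @ weight + offset.sum()
        if convention == "average_per_allele":
            denom = 2.0 * (~miss).sum(axis=1)
            vals = np.where(denom > 0, vals / denom, 0.0)
        out[sdef.name] = vals
    return pd.DataFrame(out, index=cohort.phenotypes.index)


@dataclass
class HeterogeneityTestResult:
    """Baseline-versus-split nested model comparison for one outcome."""

    outcome: str
    baseline: pd.DataFrame   # term, coef, std_beta, pvalue
    split: pd.DataFrame
    baseline_adj_r2: float
    split_adj_r2: float
    baseline_delta_adj_r2: float  # vs parent-score-only model
    split_delta_adj_r2: float
    delta_r2: float          # split R2 - baseline R2, unadjusted
    f_statistic: float
    df1: int
    df2: int
    pvalue: float
    n: int


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (x - x.mean()) / sd


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    return model.fit()


def heterogeneity_f_test(
    cohort: CohortData,
    outcome: str,
    parent: ScoreDefinition,
    ea: ScoreDefinition | None,
    conc: ScoreDefinition,
    disc: ScoreDefinition,
    covariates=(),
    score_values: pd.DataFrame | None = None,
) -> HeterogeneityTestResult:
    """Nested F-test of the sign-split score model against the baseline.

    Baseline regresses the outcome on the parent score (plus the second
    trait's score and covariates); the split model replaces the parent with
    its concordant and discordant sub-scores. Scores are computed under the
    sum convention and standardized to unit variance within the complete-case
    analysis sample; the F statistic is
    ((SSR_base - SSR_split) / df1) / (SSR_split / df2) with df1 = 1.
    """
    defs = [parent, conc, disc] + ([ea] if ea is not None else [])
    seen = [d.name for d in defs]
    if len(set(seen)) != len(seen):
        raise ValueError(f"rank-deficient design: duplicate score names {seen}")
    if score_values is None:
        score_values = compute_scores(defs, cohort, convention="sum")
    names = [d.name for d in defs]
    covariates = list(covariates)

    data = pd.concat(
        [cohort.phenotypes[[outcome] + covariates], score_values[names]], axis=1
    )
    data = data.dropna()
    n = len(data)
    y = data[outcome].to_numpy(dtype=float)

    cols = {}
    for nm in names:
        cols[nm] = _standardize(data[nm].to_numpy(dtype=float))
    for cv in covariates:
        cols[cv] = data[cv].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=data.index)

    base_terms = [parent.name] + ([ea.name] if ea is not None else []) + covariates
    split_terms = [conc.name, disc.name] + ([ea.name] if ea is not None else []) + covariates
    only_terms = [parent.name] + covariates

    for terms, label in ((base_terms, "baseline"), (split_terms, "split")):
        M = np.column_stack([np.ones(n)] + [X[t].to_numpy() for t in terms])
        rank = np.linalg.matrix_rank(M)
        if rank < M.shape[1]:
            raise ValueError(f"rank-deficient {label} design among {terms}")

    fit_base = _fit_ols(y, X[base_terms])
    fit_split = _fit_ols(y, X[split_terms])
    fit_only = _fit_ols(y, X[only_terms])

    df1 = int(fit_base.df_resid - fit_split.df_resid)
    df2 = int(fit_split.df_resid)
    ssr_base, ssr_split = fit_base.ssr, fit_split.ssr
    f = ((ssr_base - ssr_split) / df1) / (ssr_split / df2)
    from scipy import stats as sps
    pval = float(sps.f.sf(f, df1, df2))

    sd_y = y.std(ddof=1)

    def summary(fit, terms):
        rows = []
        for t in terms:
            coef = fit.params[t]
            sd_x = 1.0 if t in names else X[t].std(ddof=1)
            rows.append(
                {"term": t, "coef": coef,
                 "std_beta": coef * sd_x / sd_y,
                 "pvalue": fit.pvalues[t]}
            )
        return pd.DataFrame(rows)

    return HeterogeneityTestResult(
        outcome=outcome,
        baseline=summary(fit_base, base_terms),
        split=summary(fit_split, split_terms),
        baseline_adj_r2=float(fit_base.rsquared_adj),
        split_adj_r2=float(fit_split.rsquared_adj),
        baseline_delta_adj_r2=float(fit_base.rsquared_adj - fit_only.rsquared_adj),
        split_delta_adj_r2=float(fit_split.rsquared_adj - fit_only.rsquared_adj),
        delta_r2=float(fit_split.rsquared - fit_base.rsquared),
        f_statistic=float(f),
        df1=df1,
        df2=df2,
        pvalue=pval,
        n=n,
    )


def random_split_control(
    parent: ScoreDefinition,
    cohort: CohortData,
    outcome: str,
    covariates=(),
    n_permutations: int = 100,
    seed: int = 0,
    ea: ScoreDefinition | None = None,
    split_sizes: tuple[int, int] | None = None,
    observed_f: float | None = None,
) -> pd.DataFrame:
    """Repeat the heterogeneity F-test over random SNP partitions of the
    parent score.

    Partitions preserve the (n_conc, n_disc) sizes of the sign-based split
    when ``split_sizes`` is given (default: an even split). Returns one row
    per permutation (f, pvalue); when ``observed_f`` is supplied the frame's
    ``attrs`` carry the empirical rank of the observed F within the
    permutation distribution.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    w = parent.weights
    m = len(w)
    n_conc = split_sizes[0] if split_sizes else m // 2

    # Pre-compute per-SNP contributions once; each permutation only re-sums.
    panel = cohort.genotypes
    variants = panel.variants.set_index("snp_id")
    present = w["snp_id"].isin(variants.index).to_numpy()
    w_present = w[present]
    cols = np.array([panel.loc(s) for s in w_present["snp_id"]])
    coded = variants.loc[w_present["snp_id"]]
    flip = coded["effect_allele"].to_numpy() != w_present["effect_allele"].to_numpy()
    weight = np.where(flip, -w_present["weight"].to_numpy(), w_present["weight"].to_numpy())
    offset = np.where(flip, 2.0 * w_present["weight"].to_numpy(), 0.0)
    G = np.where(np.isnan(panel.dosages[:, cols]), 0.0, panel.dosages[:, cols])
    contrib = G * weight[None, :] + offset[None, :]

    other_vals = None
    if ea is not None:
        other_vals = compute_scores([ea], cohort, convention="sum")[ea.name]

    data = cohort.phenotypes[[outcome] + list(covariates)].copy()
    if other_vals is not None:
        data["_ea"] = np.asarray(other_vals)
    keep = data.notna().all(axis=1).to_numpy()
    data = data[keep]
    contrib = contrib[keep]
    n = len(data)
    y = data[outcome].to_numpy(dtype=float)

    fixed = [np.ones(n)]
    if other_vals is not None:
        fixed.append(_standardize(data["_ea"].to_numpy(dtype=float)))
    fixed.extend(data[cv].to_numpy(dtype=float) for cv in covariates)
    F_fixed = np.column_stack(fixed)

    def ssr(X: np.ndarray) -> float:
        _, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
        if res.size:
            return float(res[0])
        r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(r @ r)

    parent_vec = contrib.sum(axis=1)
    rows = []
    m_present = contrib.shape[1]
    for _ in range(n_permutations):
        idx = rng.permutation(m_present)
        conc_vec = contrib[:, idx[:n_conc]].sum(axis=1)
        disc_vec = parent_vec - conc_vec
        Xb = np.column_stack([F_fixed, _standardize(parent_vec)])
        Xs = np.column_stack(
            [F_fixed, _standardize(conc_vec), _standardize(disc_vec)]
        )
        ssr_b, ssr_s = ssr(Xb), ssr(Xs)
        df2 = n - Xs.shape[1]
        f = max(ssr_b - ssr_s, 0.0) / (ssr_s / df2)
        from scipy import stats as sps
        rows.append({"f": f, "pvalue": float(sps.f.sf(f, 1, df2))})

    out = pd.DataFrame(rows)
    out.attrs["seed"] = seed
    if observed_f is not None:
        out.attrs["observed_f"] = observed_f
        out.attrs["observed_rank"] = float((out["f"] < observed_f).mean())
    return out
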