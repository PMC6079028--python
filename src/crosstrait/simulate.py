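"""Synthetic GWAS study generator.

Produces every input the cross-trait pipeline consumes, with the statistical
structure the analyses assume: LD-blocked genotypes (latent Gaussian blocks
thresholded to Hardy-Weinberg dosages), a mixture genetic architecture with
concordant, discordant, and trait-specific effect classes, a quantitative
proxy trait and a liability-threshold case-control target trait measured in
sample-disjoint cohorts, a third case-control trait sharing the concordant
component with the target (so trait purging has a planted truth), a
deeply-phenotyped patient cohort with symptom measures loading on the
concordant/discordant genic components, and an optional assortative-mating
mode.

With equal concordant and discordant fractions the implied cross-trait
effect-size correlation is ~0 while half the causal loci are shared — the
dependence-without-correlation pattern the pipeline is designed to detect.

Everything is bit-reproducible from (spec, seed); per-stage seeds are spawned
from one seed sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ld import GenotypePanel
from .pgs import CohortData
from .sumstats import CaseControlDesign, SumStats

logger = logging.getLogger(__name__)

CLASSES = ("concordant", "discordant", "specific_a", "specific_b", "null")


@dataclass
class ArchitectureSpec:
    """Study-design parameters of the synthetic generator.

    Defaults are sized so a full pipeline run stays within desk scale
    (minutes on one CPU): 20,000 SNPs in 2,000 LD blocks, GWAS cohorts of
    20,000, a reference panel of 500, and a patient cohort of 1,000.
    Heritabilities mirror common estimates for a cognitive quantitative trait
    (h² = 0.25) and the liability scale of a psychiatric disorder
    (h² = 0.21); disease prevalence defaults to 5%, kept above clinical
    point-prevalence so case ascertainment stays tractable at these cohort
    sizes.
    """

    m_snps: int = 20_000
    n_blocks: int = 2_000
    within_block_r: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    # mixture fractions over SNPs (must sum to 1); sparse so that causal
    # loci are rare relative to LD blocks and two-stage selection has
    # genuine discriminating power, mirroring GWAS hit sparsity
    f_concordant: float = 0.02
    f_discordant: float = 0.02
    f_specific_a: float = 0.01
    f_specific_b: float = 0.01
    h2_a: float = 0.25
    h2_b: float = 0.21
    # third trait: shares the concordant component of trait b
    h2_c: float = 0.21
    shared_fraction_c: float = 0.5
    prevalence_k: float = 0.05
    prevalence_c: float = 0.05
    #: per-SNP effect-size variance coupled to allele frequency as
    #: (2 maf (1-maf))**(-af_coupling); 0 = uncoupled (model assumption)
    af_coupling: float = 0.0
    # symptom -> (loading on concordant component, on discordant, noise sd)
    symptom_loadings: dict = field(
        default_factory=lambda: {
            "symptom_het": (0.3, -0.3, 0.9),
            "symptom_hom": (0.3, 0.3, 0.9),
        }
    )
    # cohort sizes
    n_gwas_a: int = 20_000
    n_gwas_b: int = 20_000
    n_gwas_c: int = 12_000
    n_reference: int = 500
    # symptom regressions run on cases only; 1000 cases matches the analysis
    # n of the replication-cohort prediction models this emulates
    n_patient_cases: int = 1_000
    n_patient_controls: int = 1_000
    n_pcs: int = 10
    # genome layout
    n_chromosomes: int = 22
    snp_spacing_bp: int = 2_000
    block_spacing_bp: int = 500_000

    @property
    def f_null(self) -> float:
        return 1.0 - (
            self.f_concordant + self.f_discordant
            + self.f_specific_a + self.f_specific_b
        )

    def __post_init__(self) -> None:
        if not abs(sum(self.fractions().values()) - 1.0) < 1e-12:
            raise ValueError("class fractions must sum to 1")
        if self.f_null < -1e-12:
            raise ValueError("class fractions exceed 1")
        for h2 in (self.h2_a, self.h2_b, self.h2_c):
            if not 0 <= h2 <= 1:
                raise ValueError("heritabilities must lie in [0, 1]")
        if not 0 < self.prevalence_k < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.m_snps < self.n_blocks:
            raise ValueError("need at least one SNP per block")

    def fractions(self) -> dict[str, float]:
        return {
            "concordant": self.f_concordant,
            "discordant": self.f_discordant,
            "specific_a": self.f_specific_a,
            "specific_b": self.f_specific_b,
            "null": max(self.f_null, 0.0),
        }

    def implied_rg(self) -> float:
        """Closed-form correlation of true effect sizes across the two
        traits implied by the mixture (half-normal shared-sign classes):
        (f_c - f_d) scaled by the per-class effect-size products."""
        m = self.m_snps
        counts = {k: int(round(v * m)) for k, v in self.fractions().items()}
        m_a = counts["concordant"] + counts["discordant"] + counts["specific_a"]
        m_b = counts["concordant"] + counts["discordant"] + counts["specific_b"]
        if m_a == 0 or m_b == 0 or self.h2_a == 0 or self.h2_b == 0:
            return 0.0
        sd_a = np.sqrt(self.h2_a / m_a)
        sd_b = np.sqrt(self.h2_b / m_b)
        cov = (counts["concordant"] - counts["discordant"]) * (2 / np.pi) * sd_a * sd_b
        return float(cov / np.sqrt(self.h2_a * self.h2_b))


def _block_sizes(spec: ArchitectureSpec, rng: np.random.Generator) -> np.ndarray:
    """Variable block sizes (mean m/n_blocks, uniform spread) summing to m.

    Size variation is what gives LD scores a real spread across SNPs —
    a SNP in a 19-SNP block tags far more variation than a singleton — which
    the LD-score regressions rely on for identification.
    """
    base = spec.m_snps // spec.n_blocks
    if base == 1:
        sizes = np.ones(spec.n_blocks, dtype=int)
    else:
        sizes = rng.integers(1, 2 * base, spec.n_blocks)
    diff = spec.m_snps - int(sizes.sum())
    while diff != 0:
        i = int(rng.integers(spec.n_blocks))
        if diff > 0:
            sizes[i] += 1
            diff -= 1
        elif sizes[i] > 1:
            sizes[i] -= 1
            diff += 1
    return sizes


def make_variants(spec: ArchitectureSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Variant map: variable-size LD blocks spread evenly over chromosomes,
    SNPs evenly spaced within blocks, random biallelic coding, MAF uniform
    in range."""
    sizes = _block_sizes(spec, rng)
    block_ids = np.repeat(np.arange(spec.n_blocks), sizes)
    blocks_per_chrom = int(np.ceil(spec.n_blocks / spec.n_chromosomes))
    chrom_of_block = (np.arange(spec.n_blocks) // blocks_per_chrom) + 1
    within_chrom_block = np.arange(spec.n_blocks) % blocks_per_chrom

    chrom = chrom_of_block[block_ids].astype(str)
    block_start = within_chrom_block[block_ids] * spec.block_spacing_bp + 1
    offset = np.concatenate(
        [np.arange(s) * spec.snp_spacing_bp for s in sizes]
    )
    pos = block_start + offset

    alleles = np.array(list("ACGT"))
    ea = rng.integers(0, 4, spec.m_snps)
    oa = (ea + rng.integers(1, 4, spec.m_snps)) % 4
    maf = rng.uniform(*spec.maf_range, spec.m_snps)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(spec.m_snps)],
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "effect_allele": alleles[ea],
            "other_allele": alleles[oa],
            "block": block_ids,
            "maf": maf,
        }
    )


def simulate_genotypes(
    spec: ArchitectureSpec,
    n_individuals: int,
    seed,
    variants: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Dosages (n x m, int8) with block-exchangeable LD.

    Each haplotype's block is a latent Gaussian with exchangeable correlation
    ``within_block_r``, thresholded at the normal quantile of each SNP's MAF;
    the dosage is the sum of two independent haplotypes, so each SNP is in
    Hardy-Weinberg proportion at its MAF and blocks are mutually independent.
    """
    rng = np.random.default_rng(seed)
    if variants is None:
        variants = make_variants(spec, rng)
    r = spec.within_block_r
    thresh = stats.norm.ppf(variants["maf"].to_numpy())
    blocks = variants["block"].to_numpy()
    starts = np.flatnonzero(np.r_[True, blocks[1:] != blocks[:-1]])
    bounds = np.r_[starts, blocks.size]

    dosages = np.empty((n_individuals, blocks.size), dtype=np.int8)
    sq_r, sq_1r = np.sqrt(r), np.sqrt(1 - r)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        bs = hi - lo
        u = rng.standard_normal((n_individuals, 2, 1))
        eps = rng.standard_normal((n_individuals, 2, bs))
        z = sq_r * u + sq_1r * eps
        alleles = z < thresh[lo:hi]
        dosages[:, lo:hi] = alleles.sum(axis=1, dtype=np.int8)
    return dosages, variants


def draw_effects(
    spec: ArchitectureSpec, seed, variants: pd.DataFrame
) -> pd.DataFrame:
    """Per-SNP truth table: class labels and true standardized effects on
    traits a, b and c.

    Effects are Normal with per-class variance scaled so each trait's total
    genic variance equals its h²; concordant-class SNPs share the sign on a
    and b, discordant-class SNPs have opposite signs. Trait c's effects are
    trait b's concordant-component effects rescaled to ``shared_fraction_c``
    of h2_c plus its own specific effects on a fresh subset of null SNPs.
    With ``af_coupling`` > 0, per-SNP effect variance scales as
    (2 maf (1 - maf))**(-af_coupling), renormalized to the same h².
    """
    rng = np.random.default_rng(seed)
    m = spec.m_snps
    counts = {k: int(round(v * m)) for k, v in spec.fractions().items()}
    counts["null"] = m - sum(v for k, v in counts.items() if k != "null")

    labels = np.concatenate(
        [np.full(counts[k], k) for k in CLASSES]
    )
    labels = labels[rng.permutation(m)]

    conc = labels == "concordant"
    disc = labels == "discordant"
    spa = labels == "specific_a"
    spb = labels == "specific_b"

    m_a = int(conc.sum() + disc.sum() + spa.sum())
    m_b = int(conc.sum() + disc.sum() + spb.sum())

    # AF-coupled per-SNP variance profile (1.0 when uncoupled)
    maf = variants["maf"].to_numpy()
    het = 2 * maf * (1 - maf)
    profile = het ** (-spec.af_coupling)

    def scaled_effects(mask: np.ndarray, total_var: float) -> np.ndarray:
        k = int(mask.sum())
        out = np.zeros(m)
        if k == 0 or total_var == 0:
            return out
        w = profile[mask]
        var = total_var * w / w.sum()
        out[mask] = rng.standard_normal(k) * np.sqrt(var)
        return out

    causal_a = conc | disc | spa
    causal_b = conc | disc | spb
    beta_a = scaled_effects(causal_a, spec.h2_a)
    beta_b_raw = scaled_effects(causal_b, spec.h2_b)

    beta_b = beta_b_raw.copy()
    sign_a = np.sign(beta_a)
    beta_b[conc] = np.abs(beta_b_raw[conc]) * sign_a[conc]
    beta_b[disc] = -np.abs(beta_b_raw[disc]) * sign_a[disc]

    # trait c: shared concordant component + its own specific loci
    beta_c = np.zeros(m)
    v_conc = float((beta_b[conc] ** 2).sum())
    if v_conc > 0 and spec.h2_c > 0:
        s = np.sqrt(spec.shared_fraction_c * spec.h2_c / v_conc)
        beta_c[conc] = s * beta_b[conc]
    null_idx = np.flatnonzero(labels == "null")
    n_spec_c = min(counts["specific_b"], null_idx.size)
    spec_c_idx = rng.choice(null_idx, size=n_spec_c, replace=False)
    mask_c = np.zeros(m, dtype=bool)
    mask_c[spec_c_idx] = True
    beta_c += scaled_effects(mask_c, (1 - spec.shared_fraction_c) * spec.h2_c)

    truth = variants[["snp_id", "chrom", "pos", "maf", "block"]].copy()
    truth["class"] = labels
    truth["specific_c"] = mask_c
    truth["beta_a"] = beta_a
    truth["beta_b"] = beta_b
    truth["beta_c"] = beta_c
    return truth


def _standardize_dosages(dosages: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Theoretical standardization (2maf mean, HWE variance)."""
    return (dosages.astype(float) - 2 * maf) / np.sqrt(2 * maf * (1 - maf))


def _genic_values(dosages, truth, beta_col: str, chunk: int = 4096) -> np.ndarray:
    maf = truth["maf"].to_numpy()
    beta = truth[beta_col].to_numpy()
    nz = np.flatnonzero(beta)
    n = dosages.shape[0]
    g = np.zeros(n)
    for lo in range(0, nz.size, chunk):
        cols = nz[lo : lo + chunk]
        X = _standardize_dosages(dosages[:, cols], maf[cols])
        g += X @ beta[cols]
    return g


def component_values(dosages, truth, trait: str = "b") -> pd.DataFrame:
    """Standardized concordant- and discordant-component genic values of the
    given trait for each individual (the latent axes symptoms load on)."""
    out = {}
    beta = truth[f"beta_{trait}"].to_numpy()
    for comp in ("concordant", "discordant"):
        mask = (truth["class"] == comp).to_numpy()
        masked = truth.copy()
        masked[f"beta_{trait}"] = np.where(mask, beta, 0.0)
        g = _genic_values(dosages, masked, f"beta_{trait}")
        v = float((beta[mask] ** 2).sum())
        out[f"g_{comp}"] = g / np.sqrt(v) if v > 0 else g
    return pd.DataFrame(out)


def simulate_phenotypes(
    dosages: np.ndarray,
    truth: pd.DataFrame,
    spec: ArchitectureSpec,
    seed,
) -> pd.DataFrame:
    """Phenotypes for one cohort: quantitative trait a, liability/case
    status for traits b and c, and symptom measures (cases only).

    Trait a is genic value plus Normal noise to unit variance; b and c are
    liability-threshold binary traits; each symptom is its stated loadings
    on the individual's standardized concordant/discordant components of
    trait b plus noise, defined only where case_b is 1.
    """
    rng = np.random.default_rng(seed)
    n = dosages.shape[0]
    out = pd.DataFrame(index=pd.RangeIndex(n))

    g_a = _genic_values(dosages, truth, "beta_a")
    out["trait_a"] = g_a + rng.standard_normal(n) * np.sqrt(max(1 - spec.h2_a, 0))

    g_b = _genic_values(dosages, truth, "beta_b")
    liab_b = g_b + rng.standard_normal(n) * np.sqrt(max(1 - spec.h2_b, 0))
    thr_b = stats.norm.isf(spec.prevalence_k)
    out["liability_b"] = liab_b
    out["case_b"] = (liab_b > thr_b).astype(int)

    g_c = _genic_values(dosages, truth, "beta_c")
    liab_c = g_c + rng.standard_normal(n) * np.sqrt(max(1 - spec.h2_c, 0))
    thr_c = stats.norm.isf(spec.prevalence_c)
    out["case_c"] = (liab_c > thr_c).astype(int)

    comps = component_values(dosages, truth, trait="b")
    out[["g_concordant", "g_discordant"]] = comps.to_numpy()
    case = out["case_b"].to_numpy().astype(bool)
    for name, (lam_c, lam_d, noise_sd) in spec.symptom_loadings.items():
        sym = (
            lam_c * out["g_concordant"].to_numpy()
            + lam_d * out["g_discordant"].to_numpy()
            + rng.standard_normal(n) * noise_sd
        )
        out[name] = np.where(case, sym, np.nan)
    return out


def run_gwas(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    phenotype: np.ndarray,
    kind: str = "linear",
    trait_label: str = "",
    design: CaseControlDesign | None = None,
    chunk: int = 2048,
) -> SumStats:
    """Per-SNP association scan on one cohort.

    ``linear``: single-SNP least squares of the phenotype on raw dosage.
    ``case_control``: the same least-squares scan on 0/1 case status with
    effect and standard error rescaled by 1 / (ybar (1 - ybar)) — the
    standard score-test approximation to per-SNP logistic regression, exact
    in z and accurate in beta for small effects. Monomorphic SNPs are
    dropped and recorded in ``df.attrs['monomorphic']``.
    """
    if kind not in ("linear", "case_control"):
        raise ValueError(f"unknown GWAS kind {kind!r}")
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n != dosages.shape[0]:
        raise ValueError("phenotype length must match genotype rows")
    yc = y - y.mean()
    var_y = float(yc @ yc) / n

    m = dosages.shape[1]
    beta = np.empty(m)
    se = np.empty(m)
    eaf = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        G = dosages[:, lo:hi].astype(float)
        mean_g = G.mean(axis=0)
        Gc = G - mean_g
        var_g = (Gc * Gc).sum(axis=0) / n
        cov = yc @ Gc / n
        with np.errstate(invalid="ignore", divide="ignore"):
            b = cov / var_g
            resid = np.maximum(var_y - b * cov, 0.0) * n / (n - 2)
            s = np.sqrt(resid / (n * var_g))
        b[var_g == 0] = np.nan
        s[var_g == 0] = np.nan
        beta[lo:hi] = b
        se[lo:hi] = s
        eaf[lo:hi] = mean_g / 2.0

    if kind == "case_control":
        pbar = y.mean()
        scale = 1.0 / (pbar * (1.0 - pbar))
        beta = beta * scale
        se = se * scale

    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    df = pd.DataFrame(
        {
            "snp_id": variants["snp_id"].to_numpy(),
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "effect_allele": variants["effect_allele"].to_numpy(),
            "other_allele": variants["other_allele"].to_numpy(),
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": np.clip(pval, np.nextafter(0, 1), 1.0),
            "n_eff": float(n),
        }
    )
    mono = df["snp_id"][~np.isfinite(beta) | (eaf <= 0) | (eaf >= 1)].tolist()
    if mono:
        logger.warning("%d monomorphic SNPs dropped from %s GWAS", len(mono), trait_label)
        df = df[~df["snp_id"].isin(mono)]
    table = SumStats(df.reset_index(drop=True), trait_label=trait_label, design=design)
    table.df.attrs["monomorphic"] = mono
    return table


def simulate_case_control_cohort(
    spec: ArchitectureSpec,
    truth: pd.DataFrame,
    variants: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    seed,
    liability_col: str = "case_b",
    batch: int | None = None,
    max_batches: int = 400,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Ascertain a balanced case-control sample by batch simulation,
    keeping every case (oversampling) and controls up to quota."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    prevalence = spec.prevalence_c if liability_col == "case_c" else spec.prevalence_k
    if batch is None:
        # aim to finish case ascertainment in a couple of batches
        batch = int(np.clip(n_cases / prevalence * 0.75, 4_096, 25_000))
    got_cases: list[np.ndarray] = []
    got_controls: list[np.ndarray] = []
    pheno_cases: list[pd.DataFrame] = []
    pheno_controls: list[pd.DataFrame] = []
    n_case_acc = n_ctrl_acc = 0
    for child in ss.spawn(max_batches):
        g_seed, p_seed = child.spawn(2)
        dos, _ = simulate_genotypes(spec, batch, g_seed, variants=variants)
        pheno = simulate_phenotypes(dos, truth, spec, p_seed)
        case = pheno[liability_col].to_numpy().astype(bool)
        need_cases = n_cases - n_case_acc
        need_ctrls = n_controls - n_ctrl_acc
        if need_cases > 0:
            idx = np.flatnonzero(case)[:need_cases]
            got_cases.append(dos[idx])
            pheno_cases.append(pheno.iloc[idx])
            n_case_acc += idx.size
        if need_ctrls > 0:
            idx = np.flatnonzero(~case)[:need_ctrls]
            got_controls.append(dos[idx])
            pheno_controls.append(pheno.iloc[idx])
            n_ctrl_acc += idx.size
        if n_case_acc >= n_cases and n_ctrl_acc >= n_controls:
            break
    else:
        raise RuntimeError(
            f"could not ascertain {n_cases} cases in {max_batches} batches "
            f"(prevalence {spec.prevalence_k:g})"
        )
    dosages = np.vstack(got_cases + got_controls)
    pheno = pd.concat(pheno_cases + pheno_controls, ignore_index=True)
    return dosages, pheno


def genotype_pcs(dosages: np.ndarray, maf: np.ndarray, k: int = 10) -> np.ndarray:
    """Top principal components of standardized genotypes via the n x n
    kernel (cheap when individuals are few)."""
    n, m = dosages.shape
    K = np.zeros((n, n))
    for lo in range(0, m, 4096):
        hi = min(lo + 4096, m)
        X = _standardize_dosages(dosages[:, lo:hi], maf[lo:hi])
        K += X @ X.T
    K /= m
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))


@dataclass
class SimOutput:
    """Everything one synthetic study produces."""

    spec: ArchitectureSpec
    seed: int
    truth: pd.DataFrame
    panel: GenotypePanel
    gwas_a: SumStats          # quantitative proxy trait
    gwas_b: SumStats          # case-control target trait
    gwas_c: SumStats          # case-control shared-component trait
    patients: CohortData


def simulate_study(spec: ArchitectureSpec, seed: int = 0) -> SimOutput:
    """Generate the full study: truth, reference panel, three GWAS on
    sample-disjoint cohorts, and the patient cohort with symptoms, PCs and
    clinical covariates."""
    ss = np.random.SeedSequence(seed)
    (s_var, s_eff, s_ref, s_a, s_b, s_c, s_pat, s_cov) = ss.spawn(8)

    variants = make_variants(spec, np.random.default_rng(s_var))
    truth = draw_effects(spec, s_eff, variants)

    ref_dos, _ = simulate_genotypes(spec, spec.n_reference, s_ref, variants=variants)
    panel = GenotypePanel(
        ref_dos.astype(float),
        variants[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy(),
    )

    # cohort A: quantitative trait GWAS
    sa_g, sa_p = s_a.spawn(2)
    dos_a, _ = simulate_genotypes(spec, spec.n_gwas_a, sa_g, variants=variants)
    pheno_a = simulate_phenotypes(dos_a, truth, spec, sa_p)
    gwas_a = run_gwas(
        dos_a, variants, pheno_a["trait_a"].to_numpy(), kind="linear",
        trait_label="trait_a",
    )
    del dos_a

    # cohort B: balanced case-control GWAS on trait b
    half_b = spec.n_gwas_b // 2
    dos_b, pheno_b = simulate_case_control_cohort(
        spec, truth, variants, half_b, spec.n_gwas_b - half_b, s_b,
        liability_col="case_b",
    )
    design_b = CaseControlDesign(half_b, spec.n_gwas_b - half_b)
    gwas_b = run_gwas(
        dos_b, variants, pheno_b["case_b"].to_numpy(), kind="case_control",
        trait_label="trait_b", design=design_b,
    )
    del dos_b

    # cohort C: case-control GWAS on the shared-component trait
    half_c = spec.n_gwas_c // 2
    dos_c, pheno_c = simulate_case_control_cohort(
        spec, truth, variants, half_c, spec.n_gwas_c - half_c, s_c,
        liability_col="case_c",
    )
    design_c = CaseControlDesign(half_c, spec.n_gwas_c - half_c)
    gwas_c = run_gwas(
        dos_c, variants, pheno_c["case_c"].to_numpy(), kind="case_control",
        trait_label="trait_c", design=design_c,
    )
    del dos_c

    # patient cohort (disjoint by construction: fresh seed stream)
    dos_p, pheno_p = simulate_case_control_cohort(
        spec, truth, variants, spec.n_patient_cases, spec.n_patient_controls,
        s_pat, liability_col="case_b",
    )
    rng_cov = np.random.default_rng(s_cov)
    pcs = genotype_pcs(dos_p, truth["maf"].to_numpy(), k=spec.n_pcs)
    for i in range(spec.n_pcs):
        pheno_p[f"pc{i + 1}"] = pcs[:, i]
    n_p = len(pheno_p)
    case = pheno_p["case_b"].to_numpy().astype(bool)
    pheno_p["age_of_onset"] = np.where(
        case, np.round(rng_cov.normal(25, 6, n_p)), np.nan
    )
    pheno_p["medication"] = np.where(case, rng_cov.uniform(0, 1, n_p) < 0.7, np.nan)
    patients = CohortData(
        genotypes=GenotypePanel(
            dos_p.astype(float),
            variants[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy(),
        ),
        phenotypes=pheno_p.reset_index(drop=True),
    )

    return SimOutput(
        spec=spec, seed=seed, truth=truth, panel=panel,
        gwas_a=gwas_a, gwas_b=gwas_b, gwas_c=gwas_c, patients=patients,
    )


def assortative_mating(
    dosages: np.ndarray,
    truth: pd.DataFrame,
    spec: ArchitectureSpec,
    spouse_corr: float,
    generations: int,
    seed,
    mating_trait: str = "trait_a",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simplified assortative-mating forward simulation.

    Each generation, the cohort is split into two mating pools; mates are
    paired by rank on the mating phenotype plus noise calibrated so the
    expected spousal phenotype correlation is ``spouse_corr`` (0 = random
    mating). Offspring dosages arise by independent per-SNP Mendelian
    transmission (one Binomial(1, d/2) allele from each parent — LD within
    blocks is not preserved across generations), and phenotypes are
    regenerated from the same truth table. An odd cohort is trimmed by one.
    """
    if not 0 <= spouse_corr < 1:
        raise ValueError("spouse_corr must lie in [0, 1)")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    dos = dosages
    pheno = simulate_phenotypes(dos, truth, spec, ss.spawn(1)[0])
    for child_seed in ss.spawn(generations):
        rng = np.random.default_rng(child_seed)
        n = dos.shape[0]
        if n % 2:
            logger.warning("odd cohort size %d; dropping one individual", n)
            keep = rng.permutation(n)[: n - 1]
            dos, pheno = dos[keep], pheno.iloc[keep].reset_index(drop=True)
            n -= 1
        y = pheno[mating_trait].to_numpy()
        perm = rng.permutation(n)
        males, females = perm[: n // 2], perm[n // 2 :]
        if spouse_corr == 0:
            m_order = rng.permutation(n // 2)
            f_order = rng.permutation(n // 2)
        else:
            # sorting both pools on y + noise gives pair correlation
            # ~ var(y) / (var(y) + sigma2) between the underlying y values
            var_y = y.var()
            sigma = np.sqrt(var_y * (1 - spouse_corr) / spouse_corr)
            m_order = np.argsort(y[males] + rng.standard_normal(n // 2) * sigma)
            f_order = np.argsort(y[females] + rng.standard_normal(n // 2) * sigma)
        pa = dos[males[m_order]]
        pb = dos[females[f_order]]
        # two offspring per couple keeps the population size constant
        kids = []
        for _ in range(2):
            t_a = rng.binomial(1, pa / 2.0)
            t_b = rng.binomial(1, pb / 2.0)
            kids.append((t_a + t_b).astype(np.int8))
        dos = np.vstack(kids)
        pheno = simulate_phenotypes(dos, truth, spec, child_seed.spawn(1)[0])
    return dos, pheno
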