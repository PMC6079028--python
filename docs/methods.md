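# Methods

This note documents the statistical machinery in `crosstrait`, the design
choices behind it, and what the synthetic-data experiments do and do not
demonstrate.

## Problem setting

Two traits can be **genetically dependent** — loci associated with one are
over-represented among loci associated with the other — while their true
per-SNP effect sizes are almost **uncorrelated**. This happens when at least
one trait is genetically heterogeneous: it aggregates subphenotypes whose
architectures overlap the other trait with opposing effect signs. The
motivating case is educational attainment (EA) and schizophrenia (SZ): a
slightly positive genetic correlation coexists with strong enrichment of
EA-associated loci among SZ hits and with sign concordance near 50%. The
package implements the full analysis chain used to dissect such a pattern
and a generator that plants it.

## Summary-statistics QC (`sumstats`)

Harmonization follows the standard ladder: per-SNP coverage filter (any
monotone surrogate of per-SNP N is accepted, since some consortia release
only cohort counts), intersection of the two files on SNP id with allele
alignment (where trait b's effect allele is trait a's other allele, b's
beta is negated and its frequency folded), removal of non-ACGT or
irreconcilable allele pairs, optional removal of A/T and C/G
(strand-ambiguous) SNPs, and a two-tailed filter dropping SNPs below the
1st or above the 99th percentile of the signed difference in aligned
effect-allele frequency. The signed (not absolute) difference is used, so
the filter is symmetric two-tailed; quantiles are linear-interpolation.
Drop accounting attributes each record to its first failing rule, so rule
counts always sum to input minus output. Ambiguous-strand removal is off
for the proxy-phenotype merge and on for trait purging, which mirrors the
stricter QC appropriate when effect sizes are subtracted rather than merely
looked up. Positions are 1-based and all windows are inclusive.

`beta_from_z` converts a z-statistic to a standardized-scale beta via
`z / sqrt(n * 2 * maf * (1 - maf))`, used when a source GWAS releases only
z-scores; it is exactly inverted by `z_from_beta`.

## LD computations (`ld`)

r² is the squared Pearson correlation of unphased dosages. Pairwise queries
use pairwise-complete samples; the vectorized window computations
(clumping, LD scores, partners) mean-impute missing dosages for speed,
which is exact on complete panels (all synthetic panels are complete) and a
documented approximation otherwise.

Clumping is the greedy PLINK-style algorithm: repeatedly take the
smallest-P unassigned SNP below the threshold as a lead and absorb all
unassigned SNPs within the window whose r² with it exceeds the threshold.
SNPs absent from the panel become their own leads with a logged warning.
Very large window settings simply behave chromosome-wide. Equality with a
literal brute-force reference is property-tested over 100 random panels.

LD scores are ell_i = sum of r² with universe SNPs within the window, self
term included. The `adjusted` option replaces each r² with
`r² - (1 - r²)/(n - 2)` floored at 0, removing the ~1/n upward bias of
squared sample correlations; adjusted scores are used everywhere LDSC-type
regressions consume them.

## Proxy-phenotype method (`ppm`)

Stage one clumps the proxy trait at the preregistered threshold (default
P < 1e-5, r² > 0.1, 1000 kb). Stage two looks the leads up in the target
trait; the Bonferroni threshold is alpha divided by the number of selected
leads (the preregistered denominator — leads missing from the target file
are reported but keep the denominator).

*Sign concordance* uses the exact binomial test at p = 0.5, two-sided by
doubling the smaller tail (this convention reproduces the published 0.40
and 0.38 values; minimum-likelihood two-siding does not at two decimals).
Exactly-zero betas carry no sign and are excluded with a logged count.

*Raw enrichment* compares the observed joint-hit count against
`N_T * tau_proxy * tau_target`, the expectation if lead status on the two
traits struck independently across the N_T approximately independent loci.
The universe and the matched-null pool are clumped on the **proxy** trait
with no P filter; the target hit rate comes from clumping the target at
the Bonferroni threshold. (Clumping the pool on the target trait would
select minimum-P SNPs per block and bias the null draw toward
significance.)

*Matched-null test*: for each lead, k SNPs (default 10) are drawn from the
pool within 1 percentage point of folded MAF, without replacement globally;
leads are processed scarcest-first so processing order cannot manufacture a
shortfall. The Mann-Whitney rank-sum test (normal approximation with tie
correction) then compares lead target-P values with the matched draw;
negative z means the leads rank more significant. The negative control
compares the first matched set against the remaining sets.

*Novelty proportions* use Fisher's exact test (two-sided,
minimum-likelihood convention, cross-checked against a direct
hypergeometric enumeration).

## Effect-size credibility (`effects`)

*Winner's-curse correction.* Conditional MLE on the truncated normal: the
corrected beta maximizes the Normal(beta, se²) density of the observed
estimate restricted to the selection region |z| >= z(alpha/2), solved
numerically on [0, |beta_hat|]. For this location family the conditional
MLE solves the conditional-mean equation, so the `mean_inversion` variant
is analytically identical (both are kept as independent numerical routes
and tested for agreement). The corrected estimate is approximately
median-unbiased given selection; per-draw means over-correct near the
threshold, so the simulation check applies the correction to the mean of
the selection-conditioned draws, which recovers the true effect to <1%.

*Power* is `Phi(-c + beta/se) + Phi(-c - beta/se)` with c the alpha/2
quantile. When per-SNP standard errors are not available they are
reconstructed from the case-control design as
`sqrt(1/(2 maf (1-maf)) * (1/n_cases + 1/n_controls))`. Note the published
reference table's printed power values are not recoverable from its printed
OR/EAF/N by this (or any standard) reconstruction; when reproducing
posterior columns, power is therefore treated as an input.

*OR to R².* Cohen's d = ln(OR) sqrt(3)/pi; the MAF correction factor is
a = 1/(maf (1-maf)); R² = d²/(d² + a). The folded frequency is used, making
the conversion direction-invariant (OR and 1/OR agree).

*Posterior probability of true association* =
`power·pi / (power·pi + alpha·(1-pi))` over a grid of priors pi. The
published table's posteriors at high power are inconsistent with this
formula (power 91.0% with pi = 0.1% gives 90.2%, printed 99.0); the formula
is implemented as written and the discrepancy left visible — the
recomputed count of loci above 50% at the most conservative prior (13 of
21) matches the published count regardless.

*Implied causal count* = h²/R²_max, the equal-effects lower bound on the
number of causal loci.

## LDSC-lite (`ldsc`)

Single-trait: weighted least squares of chi²_i on N ell_i / M; slope is h²,
intercept is 1 + Na. Weights are 1/(2 E[chi²]²) with E[chi²] from the
previous pass, iterated twice from OLS. Cross-trait: z_a z_b regressed on
sqrt(N_a N_b) ell / M; the slope is the genetic covariance on the analysis
scale and the intercept absorbs correlated estimation error from sample
overlap (used by GWIS as the overlap rho). Cross weights use per-SNP
expected chi² from the per-trait fits when available, keeping the self-rg
of a table with itself at 1. Optional 20-block jackknife standard errors.
No chi² capping by default (no giant outliers in synthetic data). This is
deliberately "lite": numerical parity with the published reference
implementation is out of scope.

Two caveats established during calibration and reflected in the tests:
per-fit estimates at desk scale (thousands of SNPs, hundreds of LD blocks)
are noisy because chi² statistics are correlated within blocks and the
realized architecture itself fluctuates; and per-replicate rg ratios are
Jensen-biased upward under that noise. Aggregates therefore use the pooled
ratio mean(cov)/sqrt(mean(h2_a) mean(h2_b)) with a leave-one-replicate-out
jackknife SE, which a 200-replicate exact-model simulation confirms is
consistent.

## LD-aware enrichment (`ldaware`)

Each candidate SNP's observed Z is tested against Normal(0, v) with
v = N h² ell_i / M + intercept — the chi² its own LD score predicts under a
polygenic model — and the per-SNP P values of the (pre-clumped,
approximately independent) candidates are combined with Fisher's method,
X = -2 sum ln p ~ chi²(2k). Zero P values are clamped at 1e-300. Candidates
missing from the LD-score universe are substituted by their best panel
proxy (r² > 0.8 within 500 kb, ties by distance then id); a warning is
emitted when combined SNPs lie within 1 Mb, since proxies could reintroduce
LD that Fisher's method assumes away. h² and intercept come from `ldsc`
fits or user-supplied values. The test assumes effect size is uncorrelated
with allele frequency; the generator's `af_coupling` option exists to
demonstrate (not repair) violations of that assumption.

## GWIS trait purging (`gwis`)

The purged trait a_(min b) is the residual of the genetic regression
a = beta·b + e with beta = cov_g(a,b)/var_g(b) from the cross and
single-trait LDSC fits. Per SNP, effect_e = beta_a - beta·beta_b with
delta-method SE `sqrt(se_a² + beta² se_b² - 2 beta rho se_a se_b)`, where
rho is the estimation-error correlation estimated by the cross-trait
intercept (clamped to [-1, 1] with a warning). beta is treated as fixed; a
`beta_var` term can propagate jackknifed beta uncertainty for sensitivity.
All effects are on the common z-derived standardized scale, so var_g(b) is
the LDSC slope on the same scale. The projection should be fitted on the
same (strand-unambiguous, merged) SNP subset that is purged: fitting on a
different universe leaves subset-selection noise in the residual
covariance. The purged output is a standard summary-stat table, so the rest
of the pipeline consumes it unchanged (closure).

## Split-score heterogeneity test (`pgs`)

The parent score takes one weight (the source beta; log-OR for case-control
sources) per LD clump after an optional MAF filter. The Concordant /
Discordant split partitions the parent by sign agreement between the source
and a second trait, either after pruning (sub-scores partition the parent
exactly; LD pruned within and across) or before pruning (split first, clump
within each sign class; retains more SNPs). Scoring uses the sum convention
by default — sum of weight × dosage, weights sign-flipped when coded on the
cohort's other allele — so the parent score is exactly the sum of its
sub-scores and the baseline regression (outcome ~ parent + proxy score +
covariates) is exactly nested in the split regression (conc + disc + proxy
+ covariates); per-score standardization within the complete-case analysis
sample is affine and leaves the model spans unchanged. The F-test is
((SSR_base - SSR_split)/1) / (SSR_split/df2). The average-per-allele
convention is available for parity with common scoring tools, with the
caveat that nesting then holds only approximately. The random-split control
re-runs the test on uniformly random partitions of the parent preserving
the sign-split sizes and reports the empirical rank of the sign-based F.

## Synthetic-data generator (`simulate`)

Genotypes: each LD block is a latent Gaussian with exchangeable correlation
`within_block_r` (default 0.7) per haplotype, thresholded at each SNP's MAF
quantile; dosage is the sum of two independent haplotypes, so every SNP is
in Hardy-Weinberg proportion and blocks are independent. Block sizes vary
uniformly around the mean (m/n_blocks); this both matches real genomes
better than fixed-size blocks and gives LD scores the cross-SNP variance
the regressions need for identification. The latent correlation exceeds the
realized dosage correlation (tetrachoric attenuation), which is
intentional and irrelevant to downstream use since all LD is estimated
empirically from the panel.

Architecture: each SNP is concordant, discordant, trait-a-specific,
trait-b-specific, or null, with fractions 0.02/0.02/0.01/0.01/0.94 by
default. Effects are Normal with per-class variance scaled so each trait's
standardized genic variance equals its h² (defaults 0.25 and 0.21 —
typical for a cognitive quantitative trait and a psychiatric liability).
Concordant SNPs share the sign across traits, discordant SNPs oppose it;
with equal fractions the closed-form implied effect-size correlation is 0
while 2/3 of trait-b causal loci are shared — dependence without
correlation. The fractions are deliberately sparse: enrichment statistics
only discriminate when significant loci are rare relative to independent
blocks, as in real GWAS; a dense architecture saturates every block with
signal and the two-stage design has nothing to find. The third trait
re-uses trait b's concordant-component effects scaled to
`shared_fraction_c` of its h², plus fresh specific loci, so trait purging
has a planted truth and the residual genetic covariance after an exact
projection is zero by construction. `af_coupling` optionally scales
per-SNP effect variance as (2 maf(1-maf))^(-coupling).

Phenotypes: trait a is genic value plus Normal noise to unit variance;
traits b and c are liability-threshold binary traits (default prevalence
5% — above clinical point-prevalence so case ascertainment stays tractable
at desk scale). Case-control cohorts are ascertained by batch simulation,
keeping every case and controls to quota (balanced design; n_eff reported
as the total count). The per-SNP scan is closed-form least squares; for
case-control outcomes the linear-probability slope and SE are rescaled by
1/(ybar(1-ybar)) — the score-test approximation to per-SNP logistic
regression, exact in z and accurate for small effects. Monomorphic SNPs are
dropped and listed in `df.attrs["monomorphic"]`.

Patients: 1,000 cases + 1,000 controls by default — the case count matches
the analysis n of the replication-cohort symptom regressions this emulates
(symptoms exist only for cases). Each symptom is
`lam_c * Gc + lam_d * Gd + noise`, with Gc/Gd the standardized concordant /
discordant genic components of the target trait; defaults plant one
heterogeneous symptom (+0.3, -0.3, noise 0.9) and one homogeneous control
(+0.3, +0.3). Ten genetic PCs (computed from the patients' own genotypes),
age of onset, and a medication flag are provided as covariates.

Assortative mating (optional): mates are rank-paired on a phenotype plus
noise calibrated so sorted-pair correlation approximates the requested
spousal correlation; offspring arise by independent per-SNP Mendelian
transmission (one Binomial(1, dosage/2) allele per parent), which does not
preserve within-block LD across generations — a documented simplification.
Positive assortment on a heritable trait measurably inflates its genic
variance across generations, the classical signature.

Everything is bit-reproducible from (spec, seed); stage seeds are spawned
from a single `SeedSequence` in a fixed order so stages can be re-run in
isolation.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that each statistic is computed correctly, is
calibrated under its null, and recovers planted truth under the stated
mixture model. They do not demonstrate robustness to features of real data
the generator omits: population stratification and relatedness, MAF- and
LD-dependent architecture (beyond the optional coupling switch),
imputation error, genomic inflation from confounding, X chromosome,
multi-allelic sites, or realistic haplotype structure. Published numeric
values are reproduced only where they are pure arithmetic on printed
inputs; every data-dependent published quantity would require the original
cohort data.

## Problem sizes and numerical choices

Test and analysis runs are desk-scale by design: the shared test study uses
1,500 SNPs in 150 blocks with 6,000-sample cohorts; calibration and
recovery experiments use 2,000-8,000 SNPs, cohorts of 4,000-12,000, and
8-16 replicates (LDSC recovery: m = 4,000, 16 replicates; GWIS purging:
m = 8,000 with 1,600 blocks and strengthened h² = 0.4 / shared fraction
0.6, keeping the fitted var_g denominator of the projection safely positive
— the ratio estimator is heavy-tailed when that fit collapses; split-score
power: m = 6,000 with 1,000-case patient cohorts; null calibrations at
m = 2,000-2,500). The numbered analysis scripts default to 6,000 SNPs and
10,000-sample cohorts. Tolerances follow the statistic: exact assertions
for closed-form arithmetic (1e-12 for score additivity), printed-precision
bands for published values, binomial/KS bands for calibration rates, and
two standard errors of the replicate mean for parameter recovery.

Other numerical choices: Fisher's-method P floor 1e-300; P values clipped
away from 0 in GWAS output; quantile normal thresholds via scipy's
`isf`/`ppf`; bounded scalar minimization (tolerance 1e-12·se) for the
winner's-curse MLE; clump membership ties resolved by the ascending-P
greedy order with stable sorting, proxy ties by higher r², then smaller
distance, then lexicographic id.
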