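# Methods

`comorbigen` implements a cross-disorder genetic-overlap analysis between
two complex diseases — a schizophrenia-like trait (trait 1) and a type-2-
diabetes-like trait (trait 2) — as a tested pipeline over synthetic data:
cohort quality control, six pairwise GWAS, polygenic risk scores, a
permutation test for the excess of shared association signals, regional
Bayesian colocalisation, and cross-trait LD-score regression.  This note
records the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic data can and cannot show.

## The synthetic study

Real analyses of this design consume access-controlled genotypes and large
consortium summary statistics, so the package carries a first-class
generator (`comorbigen.synthetic_data`) whose defaults define the study
conditions used throughout the tests and the acceptance script.

**Genotypes.** Variants live in LD blocks (default 4,800 variants in 120
blocks, 5 kb spacing within a block, 500 kb gaps between blocks spread
over 22 chromosome labels).  Within a block each *haplotype* is a latent
Gaussian AR(1) chain with parameter `rho` (default 0.8) thresholded at the
allele-frequency quantile (MAF ~ Uniform(0.05, 0.5)); an individual's
dosage is the sum of two independent haplotypes.  This gives exact
Hardy-Weinberg genotypes, tunable within-block r² (~0.3 for adjacent
pairs at `rho = 0.8`) and exactly zero LD across blocks — the block
independence the colocalisation model assumes.  The variant count is the
smallest that leaves, after LD pruning at r² ≤ 0.1, enough
quasi-independent markers (~1,700) for the method-of-moments pi_hat to
separate unrelated pairs from the 0.2 relatedness threshold across the
cohort's ~5.6 million pairs; with fewer markers the estimator's noise
mass-flags unrelated pairs.  One percent of calls are set missing
completely at random and per-variant info scores are drawn
Uniform(0.3, 1.0) so the info filter has work to do.

**Phenotypes.** Two liabilities, `l_t = sum_j g_std_j beta_tj + e_t`, with
280 causal variants specific to each trait and 100 shared (beta ~ N(0,
0.03²) on the standardized-genotype scale), liability heritability 0.4 and
prevalence 0.10 for both traits.  The shared set's effect-size vectors are
orthogonalised so the *realized* genome-wide genetic correlation is exactly
zero: the two diseases share loci, not effect directions — the regime in
which a strong excess of shared signals coexists with a null genome-wide
correlation.  The comorbidity itself is modelled as a partly non-genetic
pathway: a susceptible 22% of trait-1 cases receive +2.2 liability SD on
trait 2 (a medication/lifestyle route).  Cases are individuals above the
empirical (1 − prevalence) liability quantile; the four groups
(trait-1-only, trait-2-only, comorbid, unaffected controls) are
down-sampled from a 20x rejection pool to exactly 924 / 822 / 505 / 1,125.

Two consequences of this construction are worth stating because they shape
the expected risk-score pattern.  First, the comorbid group is a mixture of
"genetic" and "environmental" trait-2 cases, so its mean trait-2 genetic
burden falls strictly between the trait-1-only and trait-2-only groups
while its trait-1 burden matches the trait-1-only group.  Second, the
trait-1-only group is *selected against* trait-2 liability (being a
trait-1 case and not a trait-2 case removes the boosted individuals), so
its trait-2 score sits slightly below, not above, the controls; the
cross-score association nevertheless stays non-significant at these sizes.
A four-group monotone chain that places controls strictly below the
trait-1-only group on the trait-2 score is incompatible with a
cross-association null under this (or any purely pleiotropic) model, so
the package tests the three-patient-group ordering, which is the pattern
the study design is about.

**Base summary statistics.** Per variant, `E[z_t] = sqrt(N_t) * beta_t *
scale` with unit-variance noise (correlated across studies only when they
share samples: corr = N_s / sqrt(N1 N2)); `se = 1 / sqrt(2 N_t p (1-p))`,
`beta = z * se`, two-sided normal p.  Defaults N1 = 70,000, N2 = 80,000,
no sample overlap, `scale = 0.4`, which yields ~35-45 genome-wide
significant hits per study — the scale of the real "established variant"
lists.  The generator does not model LD leakage into neighbouring
variants' z-scores, realistic allele-frequency spectra, or imputation
uncertainty beyond the scalar info score; passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those properties of real data.

Everything is deterministic given (spec, seed); per-stage seeds derive
from one integer through `numpy` seed sequences.

## Quality control

Filter order: sample call rate (< 0.90 removed), heterozygosity outliers
(|het rate − mean| > 3 SD, recomputed on call-rate survivors), related
pairs (pi_hat > 0.2; the lower-call-rate member is removed, ties broken
against the lexicographically later id), MDS outliers (> 3 SD on either of
the first two components), then variant filters (call rate < 0.98, HWE
exact p < 1e-4 on all samples pooled, info < 0.4, MAF < 0.01), each with
every violated reason recorded.

* The HWE test is the exact conditional test: the two-sided p sums the
  probabilities of all heterozygote counts (same allele totals) no more
  probable than the observed one, evaluated with log-factorials and
  checked exhaustively against rational-arithmetic enumeration for all
  tables with n ≤ 50.
* pi_hat uses the method-of-moments IBD estimator (IBS sharing counts
  against their expectations under in-sample allele frequencies, per pair
  over jointly observed variants).  The IBD-state chain is left unclamped
  until the final estimate — clamping the intermediate proportions to
  [0, 1] truncates the P(IBD=0) estimate at 1 and biases pi_hat upward by
  roughly a factor of two for unrelated pairs.  Small-sample frequency
  corrections (as in the classical genotype-QC toolkit) are omitted; the
  residual positive offset (~0.01-0.02) is immaterial at the 0.2
  threshold.  For the all-pairs screen the estimator runs on an LD-pruned
  (r² ≤ 0.1) marker subset, since LD inflates its variance; pairs with
  fewer than 100 jointly observed markers are not evaluated.
* Ancestry components are classical (Torgerson) MDS of the 1 − IBS
  distance matrix: double-centred squared distances, top-k
  eigendecomposition, coordinates scaled by sqrt(eigenvalue), each
  component sign-fixed so its largest-magnitude loading is positive.

## GWAS

Each comparison (three patient groups vs controls plus the three case-case
pairs) is an additive logistic regression of group membership on expected
dosage plus the first ten MDS components.  Missing dosages are mean-imputed
per variant within the analysis sample.  The fits run as batched
Newton/IRLS across all variants simultaneously (max 25 iterations,
log-likelihood tolerance 1e-8); Wald tests give the p-values.
Non-convergent fits and (quasi-)separation (|log OR| > 15 or SE > 100) are
flagged and reported without a p-value.  The implementation is checked to
1e-6 against a direct Newton maximiser of the log-likelihood.

The genomic inflation factor is the median of the 1-df chi-square
back-transform of the p-values divided by 0.454936...  On null simulations
it sits in [0.95, 1.05] at 20,000 variants.  On the default study the
per-comparison lambdas exceed 1 (up to ~1.4): with ~8% of variants truly
causal at these effect sizes the median test statistic is genuinely
shifted — polygenic signal, not confounding.  The real study's
published near-1 lambdas reflect its much lower causal density and power.

## Polygenic risk scores

Weights are log odds ratios from a base study; alleles are reconciled to
the target orientation (direct match; swap with weight negation; strand
flip via complements; palindromic A/T and C/G variants removed as
unresolvable), and scores are the mean weighted effect-allele count with
missing dosages replaced by 2×EAF (in-sample).  Clumping is the greedy
p-value-informed rule (index = smallest p among unclaimed variants;
unclaimed variants within ±250 kb at r² > 0.1 to the index are dropped),
with r² computed from the target dosages over jointly non-missing samples
and ties in p broken by variant id for determinism.

Scores are evaluated by two logistic models — full (phenotype ~ score +
C1..C10) and null (covariates only) — each summarised by Nagelkerke's
pseudo-R² against the intercept-only likelihood, `R2_CS = 1 − exp(2(ll0 −
ll)/n)` rescaled by `1 − exp(2 ll0 / n)`; the reported effect size is
`R2_final = R2_full − R2_null` (an exact floating-point difference) and
the association p is the Wald p of the score term in the full model.  Sex
is never a covariate.  Raw and standardized scores are both available;
R² and p are invariant to affine rescaling.  The threshold sweep clumps
once on the full base/target intersection and then restricts to base
p < P_t at the ten cumulative thresholds {5e-8, 0.001, 0.005, 0.05, 0.1,
0.2, 0.3, 0.4, 0.5, 1}; the down-sampling analysis redraws both groups at
n = 500 and averages R²_final and p over replicates.

## Excess of shared signals

All variants present in both studies are LD-pruned to an approximately
independent set, 2×2 tables count variants below/above each of the ten
cumulative thresholds {0.5, 0.1, 0.05, 0.04, 0.03, 0.02, 0.01, 0.005,
0.001, 5e-4} in each study (strict < below), and the Pearson chi-square
(no continuity correction) gives the overlap p.  The empirical p permutes
one study's p-values against the other within the pruned set: at a fixed
threshold both marginals are invariant under the shuffle, so the permuted
concordant count is exactly hypergeometric and is sampled directly (B
seeded draws; tables with a zero marginal contribute chi-square 0).  This
is an algebraic reduction of the shuffle, not an approximation, and is
verified against literal index shuffles.  The empirical p is a plain
proportion by default, so exact zeros are reportable; an add-one estimator
is available.

The pruning priority is a config choice among {study1, study2, min}.  The
default is **study1**, not min(p1, p2): ranking by the joint minimum makes
a variant's retention depend on both studies, which induces a
Berkson-style negative dependence between the two p-value columns of the
retained set.  The within-set permutation cannot reproduce that selection
effect, and at this package's synthetic signal density the min-ranked null
test rejects almost always at permissive thresholds.  Ranking by one
study's p keeps the other study's p-values exactly independent of
retention under trait independence, making the permutation test exactly
calibrated (verified: type-I error within [0.03, 0.07] over 1,000 null
simulations).  In data where causal variants are a vanishing fraction of
the pruned set the distinction is negligible.

## Regional colocalisation

Per LD block with m shared variants, the per-variant log approximate Bayes
factor is `0.5 log(1−r) + z² r / 2` with `r = W/(se² + W)` (prior effect
variance W = 0.04 per trait, checked against numerical integration of the
normal prior-likelihood product).  Configuration evidence is accumulated
in log space: S1 = Σ p1·ABF1_i, S2 = Σ p2·ABF2_i, S3 = Σ p12·ABF1_i·ABF2_i
(one shared causal variant), S4 = Σ_{i≠j} p1·p2·ABF1_i·ABF2_j (two
distinct causal variants, computed as the product of sums minus the
diagonal via log1p), and the no-causal hypothesis carries the residual
prior mass 1 − m(p1+p2+p12) − m(m−1)p1p2.  Default per-SNP priors are
p1 = p2 = 1e-4 and p12 = 1e-5 — conventional values, chosen here because
the study describes the method without parameters.  PP4 is identically 0
for single-variant blocks; posteriors sum to 1 to 1e-9; log-space
evaluation keeps |Z| in the 30-40 range finite.  The hypothesis numbering
follows the study design (H3 = shared, H4 = distinct), which is swapped
relative to a widely used software convention; `numbering="coloc"`
relabels the output.  Blocks with ≥ 0.9 posterior for H3 or H4 are
flagged, and the per-trait maximum |Z| is reported with all tied variant
ids.  Blocks with no shared variants are skipped during a genome scan,
not errored.

## LD-score regression

LD scores from a reference panel (≥ 50 samples) are windowed sums of
bias-adjusted squared correlations, `r²_adj = r² − (1 − r²)/(n − 2)`,
including the self term.  Heritabilities come from weighted regressions of
per-variant chi-square on the LD score (slope = N h2 / M), the genetic
covariance from the cross-trait regression of z1·z2 (slope = sqrt(N1 N2)
rho_g / M) with a free intercept that absorbs sample overlap, and
`rg = rho_g / sqrt(h2_1 h2_2)`, reported even outside [−1, 1] with an
out-of-range flag.  Weights are 1/max(l, 1) — a single-pass
heteroskedasticity proxy; the reference implementation's iterative
weighting is deliberately out of scope.  Standard errors are a delete-one
jackknife over 200 contiguous variant blocks (contiguity keeps LD leakage
between blocks minimal); constant LD scores are rejected as a degenerate
design (with a relative tolerance, since exactly constant inputs survive
floating-point centring).  Intercepts are unconstrained.

## Problem sizes and reproducibility

The default study (3,376 cohort samples × 4,800 variants, pool 67,520) was
chosen so the full pipeline — simulation, QC, six GWAS, scores, overlap
test with 10⁶ permutation draws, colocalisation and LD-score regression —
completes in a few minutes on a single core; the test suite uses smaller
cohorts for unit-level checks and the default study for the
pattern-reproduction tests.  Identical seeds give byte-identical pipeline
outputs (hashed in the run manifest); the acceptance script
(`scripts/acceptance.py`) recomputes every headline number from scratch at
an arbitrary seed.

## Known limitations

* The generator's LD is blockwise-AR(1), not coalescent; base-study
  z-scores carry no LD leakage, so LD-aware behaviour of the overlap and
  colocalisation tests is exercised through the target panel only.
* pi_hat omits the classical small-sample corrections and assumes a
  homogeneous sample; no ancestry-robust relatedness estimator is
  provided.
* LD-score regression uses single-pass weights and unconstrained
  intercepts; liability-scale conversion and partitioned heritability are
  out of scope.
* Observed-scale quantities (risk-score R², h2) are not converted to the
  liability scale, so their magnitudes are not directly comparable to
  liability-scale estimates from real studies.
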