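# Methods

`grsm` implements a two-stage gene–environment interaction analysis for
quantitative obesity traits, from genotype quality control to a 550-test
analysis matrix, together with a synthetic cohort generator that supplies
data with known truth at desk scale.

## The statistical procedure

**Stage 1 — marginal scan.** For a trait y (BMI, body-fat %, waist and hip
circumference, waist-to-hip ratio), each SNP's minor-allele dosage g_i is
regressed by OLS:

    y = β0 + β_SNP,i g_i + β_C C + ε,

with C = (sex, age, educational attainment 1–7, drinking, smoking, 10
ancestry PCs).  The per-SNP β̂_SNP,i and their two-sided t-test P-values are
both the filter and the weights.

**Score construction.** For each threshold t in the 10-value grid
(0.0001, 0.00025, 0.0005, 0.001, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.1)
the score is GRS_t = Σ_{P_j < t} β̂_SNP,j g_j, z-scored over the analysis
sample.  Member sets are nested in t by construction.  Using the same
cohort for weights and for the interaction test is valid because the
stage-1 marginal estimates and the stage-2 interaction estimates are
asymptotically independent under the null of no interaction; the package
verifies this empirically (see below).

**Stage 2 — interaction test.** For an exposure E,

    y = β0 + β_GRS GRS_t + β_E E + β_Int GRS_t×E + β_C C + ε,

is fitted at every threshold, and the combined P-value is
min(1, 10 × min_t P_Int,t) — a Bonferroni correction over the grid, capped
at 1.  The multiplier stays 10 even when some thresholds yield empty or
inestimable fits (conservative).  For a specific exercise type the model
additionally adjusts for the 17 same-facet co-exposure columns of the
other types and their 17 GRS× interactions.  Exposure main effects come
from the same model without the GRS terms.

**The analysis matrix.** Exposures are the overall regular-exercise
indicator plus {participation 0/1, monthly frequency, per-session duration
in hours} for 18 exercise types: 55 definitions × 5 traits = 275
interaction tests and 275 main-effect tests, with study-wide significance
at α = 0.05/550 ≈ 9.1×10⁻⁵.  Frequency and duration enter in raw units
(sessions/month, hours), not standardized.  One marginal scan per trait is
reused across all exposures.

Inference throughout is by unadjusted OLS t-tests (no robust errors).
Rows with a missing exposure are dropped per analysis (complete case);
constant design columns (e.g. an exercise type with no participants in a
subsample) are dropped from the design rather than voiding the fit, and a
genuinely rank-deficient fit is flagged inestimable and excluded with a
count.

## Quality control

* **SNP funnel** (sequential, with per-stage counts): call rate ≥ 0.95 →
  Hardy–Weinberg exact P ≥ 5.7×10⁻⁷ → MAF ≥ 0.01.  The HWE test is the
  exact conditional test: given the allele counts, the probabilities of
  all heterozygote counts no more likely than the observed one are summed
  (computed by the standard ratio recurrence; the test suite checks it to
  1e-12 against an exact-integer enumeration for every table with ≤ 50
  samples).  It is applied to all samples, with no founder restriction.
* **Relatedness.**  PI-HAT = P(IBD=2) + 0.5·P(IBD=1) per pair, by
  method-of-moments inversion of observed IBS counts against their
  expectations under sample allele frequencies, computed on the post-QC,
  LD-pruned SNP set (configurable).  The raw moment estimates of P(IBD=1)
  and P(IBD=2) have strongly anticorrelated errors that cancel in the
  PI-HAT combination; PI-HAT is therefore computed from the raw estimates
  and clipped to [0,1], after which the reported probability triple is
  projected onto the simplex subject to preserving the PI-HAT identity.
  Clipping each probability first and renormalizing would destroy the
  cancellation and, at a few thousand SNPs, inflate unrelated pairs past
  the 0.125 threshold roughly a thousandfold.  Removal is greedy: while
  any kept pair has PI-HAT ≥ 0.125, drop the sample in the most violating
  pairs (ties: lower call rate, then higher sample index).  Relatedness is
  resolved before any phenotype model is fitted.
* **LD pruning.**  Sliding window (size 50, step 5) per chromosome; within
  a window the SNP with the highest VIF = 1/(1−R²) is removed (ties: later
  position) until all VIF ≤ 2.  Passes repeat until a full pass removes
  nothing, so the final set provably satisfies the window criterion — the
  contract is outcome-level, since a single left-to-right pass can leave
  violations once upstream removals shift window membership.  Missing
  dosages are mean-imputed per SNP; zero-variance SNPs have VIF 1; exact
  collinearity (R² within 1e-12 of 1) is reported as +inf.
* **Ancestry PCA.**  Mean-imputed, centered dosages scaled by the sample
  standard deviation (a `binomial` √(2p(1−p)) option is provided); top-10
  left singular vectors, with each component's largest-magnitude loading
  made positive for reproducibility.  PCs are computed after relative
  removal.

## The synthetic cohort

* **Genotypes.**  Two haplotypes per sample from a thresholded
  latent-Gaussian copula with AR(1) correlation (default ρ = 0.8) inside
  50-SNP blocks, so Hardy–Weinberg holds by construction; MAF uniform on
  (0.01, 0.5) with a 2% tail below 0.01; two subpopulations with
  Balding–Nichols divergence F = 0.01 around the base frequencies;
  per-SNP missingness uniform in (0, 0.02).  A configurable SNP fraction
  has heterozygotes thinned to half their expected count — the
  excess-homozygosity signature of genotyping error.  Duplicate pairs are
  genotype-row copies with independent missingness; parent–offspring pairs
  share exactly one haplotype (expected PI-HAT 1 and 0.5).
* **Covariates and exposures** follow the published cohort descriptives:
  female 50.6%, age ~ N(48.9, 11.0) truncated to 30–70, education a
  discretized N(5.46, 0.99) clipped to 1–7, drinking 7.3%, smoking 11.6%,
  regular exercise 41.5%.  Each exerciser reports 1–3 of 18 types
  (probabilities 0.62/0.31/0.07, mean 1.45 — matching total reported
  participations per exerciser), chosen by popularity-weighted sampling
  without replacement; per-type monthly frequencies and per-session
  durations are truncated normals with the published per-type means and
  s.d.s (e.g. jogging 14.5 ± 7.7 sessions/month, 0.70 ± 0.33 h).  Eight
  random rows have all exposure columns masked, emulating questionnaire
  non-response, to exercise the complete-case path.
* **Traits.**  y = intercept + covariate effects + genetic + β_E·E +
  β_Int·z(burden)·E + N(0, σ), where the burden is the standardized
  weighted sum of the causal dosages (default 50 causal SNPs, effects
  N(0,1)) and the genetic main component is the burden scaled so its
  variance share relative to the non-genetic part equals
  `target_genetic_r2` (default 0.02, so a regression of the trait on the
  true burden yields R² ≈ 0.02).  Default covariate effects, β_E (e.g.
  −0.286 kg/m² for regular exercise on BMI) and β_Int (−0.43, −0.62,
  −0.70, −0.70, −0.001 for BMI, BFP, WC, HC, WHR) are the published
  adjusted estimates; residual s.d.s are the published trait s.d.s scaled
  by √(1−R²) of the covariate model (3.52, 5.90, 9.21, 6.73, 0.059).
  The trait mean is re-centered to the published cohort mean.
* A single master seed drives named substreams (genotypes, relatives, HWE
  injection, missingness, covariates, phenotypes), so each stage
  regenerates independently and runs are bit-identical.

**What the generator does not emulate:** realistic LD beyond block-AR(1)
decay (no recombination maps), imputation dosage uncertainty (hard calls
only), exposure correlation structure beyond popularity weights (who jogs
is independent of who swims, given being an exerciser), age/sex structure
in exposures, and assortative or family structure beyond the injected
pairs.  Passing tests therefore demonstrate correctness of the procedure
under its own assumptions, not performance on real cohort data.

## Calibration experiments (what the tests and acceptance script compute)

* **Type-I error:** 1,000 null cohorts (n = 1,000, 2,000 independent SNPs,
  SNP main effects present, no interaction) run through the full
  estimated-GRS path.  The single-threshold interaction test at the 0.05
  filter rejects at its nominal 5% within binomial error; the ×10-capped
  combined test is conservative (rate ≤ 5%).
* **Effect recovery:** 200 cohorts (n = 2,000) generated with
  β_Int = −0.43; the interaction model fitted with the *true standardized
  burden* as the score recovers the mean within 3 empirical standard
  errors and a negative sign in ≥ 95% of replicates.  With an *estimated*
  GRS the coefficient is attenuated by corr(GRS, burden) < 1 — visible in
  `examples/04`; the recovery experiment isolates the regression machinery
  from that attenuation.
* **Two-stage independence:** under the null, the cross-SNP correlation
  between stage-1 β̂ and stage-2 interaction γ̂ is zero.  Within one
  cohort all per-SNP estimates share a single phenotype realization, so
  the single-cohort correlation statistic is over-dispersed relative to
  the iid 1/√m scale and does not tighten with n; the package averages it
  over 20 independent cohorts, which concentrates the estimate well inside
  the 3/√2000 band.
* **Numerical oracles:** the HWE recurrence against exact-integer
  enumeration (≤ 1e-12); window VIF against explicit normal equations
  (≤ 1e-8); every OLS path against statsmodels (≤ 1e-10).

Problem sizes (2,000 × 5,000 for the demo pipeline; 1,000 × 2,000 per null
replicate) were chosen so the entire calibration battery runs in minutes
on a single CPU while keeping every Monte-Carlo margin meaningful.

## Numerical and design choices

* Dosages are minor-allele counts; external weights are re-oriented to the
  genotyped minor allele (sign flip when the recorded effect allele is the
  major allele) and unmatched weights are reported, mirroring the
  published-weight (EuGRS-style) score as a comparator.
* Missing dosages are mean-imputed per SNP in scores, scans, PCA and VIF;
  per-SNP regressions use Frisch–Waugh–Lovell residualization with exact
  degrees-of-freedom bookkeeping, verified against full OLS.
* z-scores use the population (ddof = 0) standard deviation; GRS weights
  are the scan coefficients bit-for-bit (no re-fitting).
* Quartile summaries cut at the 25/50/75 percentiles with ties to the
  lower quartile; stratified GRS effects use the 0.05-filter score and
  flag strata below 30 samples.
* Whole-cohort (post-QC) z-scoring is used rather than per-analysis
  subsample z-scoring; the marginal scan is computed once per trait and
  reused across exposures.

## Known limitations

* Method-of-moments PI-HAT at desk-scale SNP counts (≤ ~5,000) has
  standard deviation ~0.025–0.05; a handful of unrelated pairs per million
  can still cross 0.125, so small demo runs remove slightly more samples
  than the injected truth.  Real analyses use 10⁵–10⁶ SNPs where this
  vanishes.
* Power at the study-wide 9.1×10⁻⁵ level with the default polygenic
  architecture (2% genetic variance over 50 SNPs) is minimal at n = 2,000;
  the demo's value is the enumeration, funnel arithmetic and invariants,
  not discovery.
* No KING-robust or ancestry-adjusted kinship, no r²-pairwise pruning
  variant, no genotype imputation, and no sex-stratified acceptance
  claims (the machinery accepts any sample subset, so stratified re-runs
  are a filter away).
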