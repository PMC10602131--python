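# Methods

## Models

A quantitative trait Y is related to a genotype G (allele dosage,
standardized to unit variance where simulated) and an environmental
factor E through two working regressions fitted in possibly different
cohorts:

* GWIS: Y = β₀ + β₁G + β₂E + β₃G×E + ε, giving the main effect β̂₁,
  the environment effect β̂₂ and the interaction effect β̂₃;
* GWAS: Y = α₀ + αG + ε, giving the marginal effect α̂.

With mediation ρ (the G→E coefficient scaled by σ_E/σ_G) the two are
linked by α = θβ₁ + ρ(σ_E/σ_G)β₂ + (μ_E + ρσ_E/σ_G)β₃.  For variants
with no interaction and no mediation, α = θβ₁: such variants define a
regression line whose slope θ can be estimated from strong instruments,
and the screening statistic

T_MR_GxE = (α̂ − θ̂β̂₁)²/var(α̂ − θ̂β̂₁), var = se_α² + θ̂²se_β₁² − 2θ̂ r se_α se_β₁,

referred to a χ²₁, tests the combined interaction + mediation
contribution of each variant.  θ̂ is the inverse-variance-weighted
slope Σwⱼα̂ⱼβ̂₁ⱼ / Σwⱼβ̂₁ⱼ², wⱼ = 1/var(α̂ⱼ), optionally iterated with
removal of instruments that themselves test positive for pleiotropy
(IMRP: re-estimate θ̂, re-test, drop instruments with p below 0.05/m,
at most 10 rounds or until θ̂ moves < 10⁻⁶).  The plug-in θ̂ is treated
as a constant in the residual variance; with hundreds of instruments
var(θ̂) is negligible, with the 19–100 instruments of the simulation
designs it contributes a ≈10% variance understatement on instrument-set
variants, which the calibration tests bound empirically.

The direct test is T_direct = β̂₃²/var(β̂₃); the difference test is
T_diff = (α̂−β̂₁)²/var(α̂−β̂₁).  When both models are fitted on the same
subjects and the marginal model is adjusted for E, the OLS
omitted-variable identity makes α̂ − β̂₁ an exact multiple of β̂₃, so
T_diff and T_direct coincide (a unit test verifies equality to machine
precision from a shared fit, and statistic correlation > 0.99 when the
covariance is supplied analytically).  The main- and
interaction-effect estimators are intrinsically correlated through the
G/G×E collinearity, corr(β̂₁, β̂₃) = −μ_E/√(μ_E²+σ_E²), which is what
robs the direct test of power when the environment mean is large.

**Two-step procedure.** Step 1 screens every variant with T_MR_GxE at
a Bonferroni level (0.05/m in simulations; 5×10⁻⁸ for genome-scale
panels — the switch is a panel-size heuristic left to the caller).
Step 2 applies T_direct to the k survivors at 0.05/(k × number of
exposures); e.g. 17 surviving signals across 4 environmental factors
give 7.35×10⁻⁴.  Both stages are counted on surviving *signals*, not
loci.

## Expected value of θ̂ and a covariance correction

Under no interaction/mediation, standardized genotypes and unit
residual variance, the expectation of the IVW slope is

E[θ̂] = [σ_β² + (n₀/(n₁n₂))·c] / [σ_β² + (1/n₂)(1 + μ_E₂²σ_E₂²)],

where σ_β² is the average per-instrument trait variance, n₀ the number
of subjects shared between the GWAS (n₁) and GWIS (n₂) cohorts, and
(μ_E₂, σ_E₂) the GWIS environment moments (shared subjects draw E from
the GWIS distribution).  `expected_theta` implements the overlap factor
c = 1 + μ_E₀²σ_E₀² by default.  That form ignores the negative
covariance between β̂₁ and β̂₃ noted above; propagating it gives c = 1
(`include_estimator_cov=True`).  The package's own Monte Carlo is
decisive: at full overlap with μ_E = 1 the default form predicts 1.0
while the simulated mean is ≈ 0.93–0.94, exactly matching the
corrected form.  The two coincide when n₀ = 0 or μ_E₀ = 0, and the
bias term vanishes for strong instruments.  `expected_theta_for_config`
additionally expresses σ_β² relative to the *shared residual variance*
(noise plus polygenic background), which is the unit the derivation's
σ² = 1 convention actually refers to; with that normalization the
corrected closed form tracks simulated means within Monte-Carlo error
across overlap/strength regimes.  E[θ̂] ≤ 1 throughout, approaching 1
for large homogeneous samples and slowly under weak instruments.

## Sample-overlap correlation r

Real-data runs estimate r as the Pearson correlation of GWAS and GWIS
z-scores over variants null in both sources (p > 0.05, at least 100
variants).  Conditioning on two truncated z's attenuates the estimate
toward zero (by roughly 15% at r = 0.6), making the screen mildly
conservative; this is inherent to the null-variant method and is
documented rather than corrected.  Simulation replicates cannot use
this estimator — the panels hold only 20–102 variants, far below the
cutoff, and a 20-variant correlation (SE ≈ 0.23) would destroy
calibration at high overlap — so `run_replicates` defaults to the
design-implied value: the shared-subject error covariance
σ_shared²·n₀/(n₁n₂) divided by the fitted standard errors, where
σ_shared² is the residual variance common to both fits (noise +
polygenic background; the environment main effect belongs only to the
unadjusted marginal fit).  A replicate-level test confirms the analytic
r reproduces the empirical error correlation.  With r specified this
way the two-step procedure holds its level at every overlap fraction,
including the full-overlap/strong-environment corner; miscalibration
there requires a misspecified r, so the package keeps the level rather
than reproducing that artefact.

## Effect standardization

`standardize_effects` converts each (β̂, se) to b = z/√n, se = 1/√n —
unit-free, z-preserving, and the convention used for real
summary-statistic screens.  Note that se_β₁ carries the G/G×E
collinearity inflation √((μ_E²+σ_E²)/σ_E²), so z-based standardization
rescales β̂₁ relative to α̂ and θ̂ absorbs that factor (expected ≈ √2
above 1 at μ_E = σ_E); this is one of the systematic between-source
differences θ exists to soak up, and it leaves the screen's residuals
and p-values meaningful.  The simulator, whose genotypes are generated
standardized, therefore works on the raw effect scale, where θ̂ has
the clean closed-form behaviour above.

## Simulation designs

*No-mediation design* (m = 102): pⱼ ~ Uniform(0.05, 0.5),
G* ~ Binomial(2, pⱼ) standardized (centered by default); main effects
β₁ⱼ ~ N(0, σ_β²) with σ_β² = 0.005 by default (≈34% trait variance
over 102 variants — lipid-like; unprinted in the source design, chosen
once); Y = ΣGβ₁ + 0.1E + 0.05·G₁E + ε, ε ~ N(0,1).  GWAS-only subjects
draw E ~ N(μ_E1, 1), GWIS and shared subjects E ~ N(μ_E2, 1); defaults
μ_E1 = μ_E2 = 1, n₁ = n₂ = 20,000.  Variant 1 carries the interaction
(power), variant 2 is the null test variant, the last 100 variants are
used directly as instruments.  A `focal_main_effect` knob reproduces
the s ∈ {−1, 0, 1} main/interaction direction scenarios.

*Mediation panel* (m = 20): G ~ Binomial(2, 0.3) standardized without
mean correction; every variant has main effect 0.1 (so the 19
non-focal variants are valid instruments); under mediation the focal
variant feeds the environment, E = 0.05·G + N(1, 0.9975), putting
0.25% of var(E) under genetic control; Y = ΣGβ₁ + γE (+ 0.1·G₁E under
model c) + N(0, 10), γ ∈ {1, 5}.  The GWIS cohort (n₂ = 20,000) is
always contained in the GWAS cohort; non-overlapping GWAS subjects get
a 1.5× environment mean.  The N(0,10) residual is interpreted as
variance 10 (configurable).

`fit_summary_stats` fits the per-variant marginal (optionally
E-adjusted) and interaction models with a vectorized batch
normal-equations solver — a replicate study performs 10⁴–10⁵ small OLS
fits, where looping a general-purpose fitter is two orders of magnitude
slower; agreement with statsmodels OLS (coefficients and standard
errors, relative 10⁻⁹) is enforced by test.  Wald p-values use the χ²₁
survival function throughout.

`run_replicates` seeds replicate i with `seed + i`, aggregates
rejection rates (per-variant at α and family-wise under the
Bonferroni/two-step scheme), and reports means and Monte-Carlo SEs of
θ̂ and of both interaction estimators — the direct β̂₃ and the MR route
(α̂ − θ̂β̂₁)/μ_E, the latter valid only without mediation and divided by
the GWAS-sample environment mean (overlap mixture).

Problem sizes: recovery studies use 500 replicates at the design
sample sizes; calibration uses 2,000 replicates of the 20-variant
panel; θ̂ studies 100–200 replicates.  These match the precision the
assertions need (2 Monte-Carlo SEs; 3 binomial SEs).

## Heritability of the screening residuals

`ldsc_h2` regresses the residual χ² = ((α̂−θ̂β̂₁)/se)² on (n/M)·ℓⱼ with
a free intercept and weights 1/max(ℓⱼ, 1); the slope is the
heritability carried by interaction + mediation, a lower bound on their
phenotypic contribution.  Standard errors come from a 20-block
contiguous jackknife (fewer blocks if variants are scarce).
Chromosome-specific fits use the chromosome's proportional share of the
denominator M, so the per-chromosome slopes sum to the genome-wide
quantity; only non-negative chromosome estimates enter the reported
total (clipping happens at the point-estimate level; the unclipped sum
is also reported).  M defaults to the number of regression variants.
LD scores are accepted as a table (SNP/CHR/L2) or generated
synthetically (shifted gamma, minimum 1) for testing; computing them
from reference genotypes is out of scope.

## Harmonization rules

Variants are matched by id, then by chrom:pos for the remainder
(position matches among multiple same-position variants require MAF
agreement within 0.01; duplicate ids keep the smallest MAF difference,
ties broken by file order).  Swapped alleles flip the GWIS effect signs
and complement its EAF; {A,T}/{C,G} pairs are strand-ambiguous and
dropped; minor-allele-frequency differences above 0.15 are dropped;
every rule's count lands in the filter log, which always satisfies
input = retained + removed.  Effective-sample-size filtering is strict
(<); exposure-associated loci are excluded within ±500 kb of each
supplied hit (window inclusive, 1-based coordinates; the source
procedure names no window, so the instrument-pruning window is reused
and exposed as a flag).  Genomic control divides the χ² by
λ = median(χ²)/0.4549 only when λ > 1, before instrument selection.
Instrument pruning is greedy in ascending p: keep a candidate iff
r² < 0.1 with every kept variant within 500 kb on the same chromosome.
Loci are 1-Mb windows around successive most-significant unassigned
variants (a partition; equidistant variants join the earlier lead), and
independent signals within a locus are chosen greedily at r² < 0.1.

## Known limitations

* The synthetic cohorts use independent variants, Gaussian environments
  and homoscedastic noise; they do not emulate LD, meta-analysis
  heterogeneity, population stratification, or binary exposures, so
  passing tests demonstrate the statistics' behaviour under the stated
  generative models, not robustness to those real-data complications.
* T_MR_GxE tests interaction *and* mediation jointly; the two-step
  procedure tests interaction only to the extent the confirmation
  stage does, and exposure-associated loci should be excluded upstream
  when mediation is a concern.
* The MR-route interaction estimate requires μ_E ≠ 0 and no mediation;
  its SE grows as the environment mean shrinks.
* A single genome-wide r is used per trait pair; variant-specific
  overlap (e.g. differing per-variant sample sizes) is approximated.
* The IMRP removal threshold, iteration cap and tolerance are
  conventions (0.05/m, 10, 10⁻⁶), all exposed as parameters.
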