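# mrgxe

Screening the genome for gene–environment (G×E) interaction and
environmental mediation using existing GWAS and GWIS summary
statistics, through the lens of Mendelian randomization (MR).

## The problem and the idea

Direct genome-wide tests of interaction are underpowered: in the
interaction model

    Y = β₀ + β₁G + β₂E + β₃G×E + ε                      (GWIS)

the collinearity between G and G×E inflates the standard error of
β̂₃, and a genome-wide search pays a multiple-testing burden of
millions of variants.  Meanwhile nearly every trait already has a much
larger GWAS of the *marginal* model

    Y = α₀ + αG + ε                                      (GWAS)

The marginal and main effects are linked by
α = θβ₁ + ρ(σ_E/σ_G)β₂ + (μ_E + ρσ_E/σ_G)β₃, where ρ is the mediation
contribution of G through E and θ is a bridging coefficient that
absorbs systematic differences between the two analyses (trait
transformations, covariates, meta-analysis artefacts).  Variants free
of interaction and mediation fall on the line α = θβ₁; variants with
either depart from it — exactly like horizontally pleiotropic variants
depart from the regression line in MR.  Treating the trait's polygenic
score as a pseudo exposure, θ is estimated by inverse-variance
weighting (IVW) over genome-wide-significant, LD-pruned instruments
(iterated with pleiotropy-outlier removal, the IMRP scheme), and each
variant is screened with

    T_MR_GxE = (α̂ − θ̂β̂₁)² / var(α̂ − θ̂β̂₁)  ~  χ²₁,

    var(α̂ − θ̂β̂₁) = se_α² + θ̂²se_β₁² − 2θ̂·r·se_α·se_β₁,

where r is the correlation of estimation errors induced by subjects
shared between the GWAS and GWIS cohorts (estimated from null
variants).  A **two-step procedure** then tests only the screen's
survivors with the direct statistic T_direct = β̂₃²/var(β̂₃), shrinking
the confirmation burden from millions of variants to a handful.
Finally, LD score regression on the screening residuals α̂ − θ̂β̂₁
bounds the share of SNP heritability contributed by interaction and
mediation.

The package provides: summary-statistics harmonization and QC
(`mrgxe.sumstats`), θ estimation and the MR screen (`mrgxe.mr`), the
direct/difference/two-step tests and locus grouping (`mrgxe.gxe`), the
residual LDSC heritability (`mrgxe.heritability`), and a simulator of
paired GWAS/GWIS cohorts for calibration and power studies
(`mrgxe.simulate`), plus a thin `mrgxe` command-line interface
(`screen`, `two-step`, `simulate`, `h2`, `make-fixtures`).

## Worked example

`examples/simulation_study.py` simulates the 20-variant mediation
panel (GWIS n = 5,000 here so the example runs in seconds), fits both
models per variant, and evaluates all three tests:

```
fully null panel (model a), alpha = 0.05:
  null_direct          0.057  [0.031, 0.083]
  null_mr              0.070  [0.041, 0.099]
  null_two_step_any    0.063  [0.036, 0.091]
mediation + interaction (model c, beta3 = 0.1):
  focal_direct_bonf    0.200  [0.155, 0.245]
  focal_mr_bonf        0.837  [0.795, 0.878]
  focal_two_step       0.570  [0.514, 0.626]
  mean direct beta3-hat = 0.1006 (+- 0.0052), generative value 0.1
```

Under the null all three rejection rates sit at the nominal 0.05
(brackets are 95% CIs over replicates).  With mediation present the MR
screen fires far more often than the direct test (0.84 vs 0.20), and
the two-step procedure converts that into nearly triple the direct
test's power at the same family-wise level, while the interaction
estimate itself stays unbiased.  `examples/theta_behaviour.py` shows
θ̂'s Monte-Carlo mean tracking its closed-form expectation (and its
attenuation below 1 under weak instruments);
`examples/screen_summary_stats.py` runs the whole file-to-loci screen
on synthetic summary statistics; `examples/interaction_heritability.py`
recovers a planted residual heritability by per-chromosome LDSC.

## Scope

The package operates on summary statistics and simulated cohorts; it
does not download or process consortium data, compute LD scores from
reference panels, or perform enrichment/colocalization analyses.
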