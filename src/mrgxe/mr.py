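"""Bridging-coefficient estimation and the MR-based G×E screening test.

The screen treats the trait's own polygenic contribution as a pseudo
exposure.  Valid instruments (genome-wide-significant, LD-pruned
variants free of interaction and mediation) satisfy the linear relation
alpha = theta * beta1 between the GWAS marginal effect and the GWIS
main effect; a variant with gene-environment interaction or mediation
through E departs from that line exactly like a horizontally
pleiotropic variant in ordinary Mendelian randomization.  The per-variant
statistic

    T_MR_GxE = (alpha - theta*beta1)^2 / var(alpha - theta*beta1)  ~  chi^2_1

therefore tests the combined interaction + mediation contribution.
``var`` accounts for GWAS/GWIS sample overlap through a single
genome-wide correlation r between the two sets of effect-estimate
errors:

    var = se_alpha^2 + theta^2 se_beta1^2 - 2 theta r se_alpha se_beta1.

theta itself is estimated by inverse-variance weighting, optionally
iterated with pleiotropy-outlier removal (the IMRP scheme).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import IndependentLD, PairwiseLD
from .sumstats import HarmonizedPanel

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def gc_lambda(chisq_values) -> float:
    """Genomic-control lambda: median chi-square over the chi^2_1 median.

    Values below 1 (deflation) are reported as-is; correction downstream
    only ever divides by lambda when it exceeds 1.
    """
    x = np.asarray(chisq_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("gc_lambda needs at least one chi-square value")
    return float(np.median(x) / CHI2_1_MEDIAN)


@dataclass
class InstrumentSet:
    """LD-pruned, genome-wide-significant instruments for theta."""

    panel: HarmonizedPanel
    p_thresh: float
    window_bp: int
    r2_max: float
    gc_lam: float = 1.0

    def __len__(self) -> int:
        return len(self.panel)

    @property
    def df(self) -> pd.DataFrame:
        return self.panel.df


@dataclass
class CausalEffect:
    """IVW/IMRP estimate of the bridging coefficient theta."""

    theta_hat: float
    se_theta: float
    n_iv: int
    overlap_corr: float = 0.0
    n_iterations: int = 1
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class GxETestResult:
    """Per-variant interaction/mediation test statistics."""

    variant_id: str
    t_mr: float
    p_mr: float
    residual: float
    se_residual: float
    t_direct: float | None = None
    p_direct: float | None = None
    t_diff: float | None = None
    p_diff: float | None = None
    interaction_mr_estimate: float | None = None
    two_step_pass: bool = False


class DegenerateInstrumentsError(RuntimeError):
    pass


def select_instruments(
    panel: HarmonizedPanel,
    p_thresh: float = 5e-8,
    window_bp: int = 500_000,
    r2_max: float = 0.1,
    ld: PairwiseLD | None = None,
    apply_gc: bool = True,
) -> InstrumentSet:
    """Pick GWAS-significant variants and greedily LD-prune them.

    Candidates must have GWAS p-value below ``p_thresh`` after genomic
    control (the chi-square is divided by lambda when ``apply_gc`` and
    lambda > 1).  Pruning walks candidates in ascending p order and keeps
    a variant iff its r^2 with every kept variant within ``window_bp``
    on the same chromosome stays below ``r2_max``.
    """
    if ld is None:
        ld = IndependentLD()
    df = panel.df
    if "p_gwas" in df.columns and df["p_gwas"].notna().all():
        chisq = stats.chi2.isf(np.clip(df["p_gwas"].to_numpy(float), 1e-320, 1.0), 1)
    else:
        z = df["alpha_hat"].to_numpy(float) / df["se_alpha"].to_numpy(float)
        chisq = z**2
    lam = gc_lambda(chisq)
    if apply_gc and lam > 1:
        chisq = chisq / lam
    pvals = stats.chi2.sf(chisq, 1)

    cand = df.assign(_p=pvals)[pvals < p_thresh].sort_values(
        "_p", kind="stable")
    kept_idx: list[int] = []
    kept_pos: dict[str, list[tuple[int, str]]] = {}
    for idx, row in cand.iterrows():
        chrom, pos, vid = str(row["chrom"]), int(row["pos"]), row["variant_id"]
        ok = True
        for kpos, kvid in kept_pos.get(chrom, ()):
            if abs(kpos - pos) <= window_bp and ld.r2(vid, kvid) >= r2_max:
                ok = False
                break
        if ok:
            kept_idx.append(idx)
            kept_pos.setdefault(chrom, []).append((pos, vid))
    if len(kept_idx) < 2:
        raise DegenerateInstrumentsError(
            f"only {len(kept_idx)} instruments survive selection; "
            "theta is not estimable")
    sub = df.loc[sorted(kept_idx)].reset_index(drop=True)
    return InstrumentSet(
        HarmonizedPanel(sub, dict(panel.filter_log), dict(panel.sources)),
        p_thresh=p_thresh, window_bp=window_bp, r2_max=r2_max, gc_lam=lam)


def estimate_overlap_corr(
    panel: HarmonizedPanel,
    p_null_min: float = 0.05,
    min_variants: int = 100,
) -> float:
    """Sample-overlap correlation from null variants' z-scores.

    Shared subjects between the GWAS and GWIS cohorts correlate the
    errors of alpha-hat and beta1-hat.  Among variants null in both
    sources (p > ``p_null_min``) the z-scores are essentially pure
    error, so their Pearson correlation estimates r.
    """
    df = panel.df
    z_alpha = df["alpha_hat"].to_numpy(float) / df["se_alpha"].to_numpy(float)
    z_beta1 = df["beta1_hat"].to_numpy(float) / df["se_beta1"].to_numpy(float)
    if "p_gwas" in df.columns and "p_gwis" in df.columns:
        p1 = df["p_gwas"].to_numpy(float)
        p2 = df["p_gwis"].to_numpy(float)
    else:
        p1 = stats.chi2.sf(z_alpha**2, 1)
        p2 = stats.chi2.sf(z_beta1**2, 1)
    null = (p1 > p_null_min) & (p2 > p_null_min)
    if null.sum() < min_variants:
        raise ValueError(
            f"only {int(null.sum())} variants have both p > {p_null_min}; "
            "relax p_null_min or supply a larger panel")
    r = float(np.corrcoef(z_alpha[null], z_beta1[null])[0, 1])
    return r


def ivw_theta(instruments: InstrumentSet | HarmonizedPanel,
              overlap_corr: float = 0.0) -> CausalEffect:
    """Inverse-variance-weighted slope of alpha-hat on beta1-hat.

    theta-hat = sum_j w_j alpha_j beta1_j / sum_j w_j beta1_j^2 with
    w_j = 1/var(alpha_j).  With standardized effects the weights are
    constant and this reduces to the simple cross-product ratio.  The
    model-based SE uses the same fixed weights.
    """
    df = instruments.df if isinstance(instruments, InstrumentSet) else instruments.df
    if len(df) < 2:
        raise DegenerateInstrumentsError("theta needs at least 2 instruments")
    alpha = df["alpha_hat"].to_numpy(float)
    beta1 = df["beta1_hat"].to_numpy(float)
    w = 1.0 / df["se_alpha"].to_numpy(float) ** 2
    denom = float(np.sum(w * beta1**2))
    if denom == 0:
        raise DegenerateInstrumentsError("all instrument main effects are zero")
    theta = float(np.sum(w * alpha * beta1) / denom)
    se = float(np.sqrt(1.0 / denom))
    return CausalEffect(theta_hat=theta, se_theta=se, n_iv=len(df),
                        overlap_corr=overlap_corr)


def residual_variance(
    se_alpha, se_beta1, theta: float, overlap_corr: float = 0.0
):
    """var(alpha - theta*beta1) with the overlap covariance term."""
    se_a = np.asarray(se_alpha, dtype=float)
    se_b = np.asarray(se_beta1, dtype=float)
    var = se_a**2 + theta**2 * se_b**2 - 2.0 * theta * overlap_corr * se_a * se_b
    return var


def t_mr_gxe_arrays(alpha, se_alpha, beta1, se_beta1, theta: float,
                    overlap_corr: float = 0.0):
    """Vectorized MR-G×E screen: (residual, se, chi-square, p) arrays."""
    alpha = np.asarray(alpha, dtype=float)
    beta1 = np.asarray(beta1, dtype=float)
    resid = alpha - theta * beta1
    var = residual_variance(se_alpha, se_beta1, theta, overlap_corr)
    if np.any(var <= 0):
        raise ValueError(
            "non-positive var(alpha - theta*beta1); the overlap correlation "
            f"{overlap_corr} is inconsistent with the standard errors")
    stat = resid**2 / var
    p = stats.chi2.sf(stat, 1)
    return resid, np.sqrt(var), stat, p


def t_mr_gxe(variant, effect: CausalEffect) -> GxETestResult:
    """MR-based interaction/mediation test for one harmonized variant."""
    resid, se, stat, p = t_mr_gxe_arrays(
        variant.alpha_hat, variant.se_alpha, variant.beta1_hat, variant.se_beta1,
        effect.theta_hat, effect.overlap_corr)
    return GxETestResult(variant_id=variant.variant_id, t_mr=float(stat),
                         p_mr=float(p), residual=float(resid),
                         se_residual=float(se))


def screen_panel(panel: HarmonizedPanel, effect: CausalEffect) -> pd.DataFrame:
    """Apply the MR-G×E screen to every variant of a panel.

    Returns the panel frame augmented with ``residual``, ``se_residual``,
    ``t_mr`` and ``p_mr`` columns.
    """
    df = panel.df
    resid, se, stat, p = t_mr_gxe_arrays(
        df["alpha_hat"], df["se_alpha"], df["beta1_hat"], df["se_beta1"],
        effect.theta_hat, effect.overlap_corr)
    return df.assign(residual=resid, se_residual=se, t_mr=stat, p_mr=p)


def imrp_estimate(
    instruments: InstrumentSet,
    overlap_corr: float = 0.0,
    pleio_alpha: float | None = None,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> CausalEffect:
    """Iterative MR-and-pleiotropy estimate of theta.

    Alternates (i) IVW estimation of theta on the current instruments,
    (ii) the pleiotropy (MR-G×E) test on every instrument, and (iii)
    removal of instruments significant at ``pleio_alpha`` (default the
    Bonferroni level 0.05/m), until the removed set stabilises, theta
    moves less than ``tol``, or ``max_iter`` rounds.
    """
    df = instruments.df.reset_index(drop=True)
    if pleio_alpha is None:
        pleio_alpha = 0.05 / len(df)
    active = np.ones(len(df), dtype=bool)
    removed: list[str] = []
    theta_prev = np.inf
    effect = None
    for it in range(1, max_iter + 1):
        sub = df[active]
        if len(sub) < 2:
            raise DegenerateInstrumentsError(
                f"fewer than 2 instruments remain at iteration {it}; "
                f"removed so far: {removed}")
        effect = ivw_theta(HarmonizedPanel(sub), overlap_corr)
        _, _, _, p = t_mr_gxe_arrays(
            df["alpha_hat"], df["se_alpha"], df["beta1_hat"], df["se_beta1"],
            effect.theta_hat, overlap_corr)
        flag = (p < pleio_alpha) & active
        converged = not flag.any() or abs(effect.theta_hat - theta_prev) < tol
        effect.n_iterations = it
        if converged:
            break
        removed.extend(df.loc[flag, "variant_id"].tolist())
        active &= ~flag
        theta_prev = effect.theta_hat
    effect.removed_ids = removed
    effect.overlap_corr = overlap_corr
    return effect


def interaction_effect_mr(variant, effect: CausalEffect,
                          mu_E: float) -> tuple[float, float]:
    """Interaction effect recovered from the margin: (alpha - theta*beta1)/mu_E.

    Valid when mediation is absent (G independent of E); both this and
    the direct GWIS estimate of beta3 are then unbiased.
    """
    if mu_E == 0:
        raise ValueError("mu_E = 0: the interaction does not reach the "
                         "marginal effect and cannot be recovered from it")
    resid, se, _, _ = t_mr_gxe_arrays(
        variant.alpha_hat, variant.se_alpha, variant.beta1_hat, variant.se_beta1,
        effect.theta_hat, effect.overlap_corr)
    return float(resid) / mu_E, float(se) / abs(mu_E)


def expected_theta(
    sigma_beta2: float,
    n1: float,
    n2: float,
    n0: float,
    mu_E0: float,
    sigma_E0: float,
    mu_E2: float,
    sigma_E2: float,
    include_estimator_cov: bool = False,
) -> float:
    """Closed-form expectation of the IVW theta-hat without interaction/mediation.

    E[theta] = [sigma_beta^2 + (n0/(n1 n2))(1 + mu_E0^2 sigma_E0^2)]
             / [sigma_beta^2 + (1/n2)(1 + mu_E2^2 sigma_E2^2)]

    with sigma_beta^2 the average per-instrument trait variance, n0 the
    GWAS/GWIS overlap count and (mu_E0, sigma_E0) the environment
    moments in the overlapping subsample.  The expression approaches 1
    as n1, n2 grow and never exceeds 1 when
    n0 (1 + mu_E0^2 sigma_E0^2) / n1 <= 1 + mu_E2^2 sigma_E2^2.

    This form treats the overlap-induced covariance of alpha-hat and
    beta1-hat as var(beta1-hat) scaled by the overlap fraction, which
    ignores the negative covariance between the main- and
    interaction-effect estimators; it is exact when n0 = 0 or
    mu_E0 = 0, and slightly optimistic otherwise.
    ``include_estimator_cov=True`` switches the overlap term to the
    covariance-corrected value n0/(n1 n2), which Monte Carlo confirms
    at full overlap with nonzero environment mean.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not 0 <= n0 <= min(n1, n2):
        raise ValueError("overlap count must satisfy 0 <= n0 <= min(n1, n2)")
    if sigma_beta2 < 0:
        raise ValueError("sigma_beta2 must be non-negative")
    overlap_term = n0 / (n1 * n2)
    if not include_estimator_cov:
        overlap_term *= 1.0 + mu_E0**2 * sigma_E0**2
    denom = sigma_beta2 + (1.0 / n2) * (1.0 + mu_E2**2 * sigma_E2**2)
    if denom == 0:
        raise ZeroDivisionError("degenerate configuration: zero denominator")
    return (sigma_beta2 + overlap_term) / denom
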