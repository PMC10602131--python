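"""Paired GWAS/GWIS cohort simulation and replicate studies.

Two generative designs are implemented:

* ``no_mediation`` — 102 independent variants with Binomial(2, p_j)
  genotypes (p_j ~ Uniform(0.05, 0.5), standardized), polygenic main
  effects beta1_j ~ N(0, sigma_beta^2), an environment main effect of
  0.1 and a G×E effect of 0.05 on variant 1:

      Y_i = sum_j G_ij beta1_j + 0.1 E_i + 0.05 G_i1 E_i + eps_i.

  The last 100 variants serve as instruments; variants 1 and 2 are the
  power and type-I test variants.  GWAS-only subjects draw
  E ~ N(mu_E1, sigma_E1^2); GWIS and overlapping subjects draw from the
  GWIS distribution N(mu_E2, sigma_E2^2).

* ``mediation_panel`` — 20 independent variants with Binomial(2, 0.3)
  genotypes standardized without mean correction, each with main effect
  0.1.  A focal variant optionally mediates through E
  (E = 0.05 G + noise, so G explains 0.25% of var(E)) and/or interacts
  (0.1 G*E).  The environment mean of non-overlapping GWAS subjects is
  1.5x the GWIS mean.  Residual variance is 10.

Per-variant model fitting uses a vectorized batch least-squares solver
(normal equations assembled from cross-product moments); its agreement
with ordinary OLS is enforced by tests against statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .mr import ivw_theta, t_mr_gxe_arrays
from .gxe import t_diff as t_diff_stat
from .sumstats import HarmonizedPanel

Design = Literal["no_mediation", "mediation_panel"]
MediationModel = Literal["a", "b", "c"]


@dataclass
class SimulationConfig:
    """Full generative parameterization of one simulation study."""

    design: Design = "no_mediation"
    m: int = 102
    n1: int = 20_000
    n2: int = 20_000
    n0: int = 0
    mu_E1: float = 1.0
    mu_E2: float = 1.0
    sigma_E1: float = 1.0
    sigma_E2: float = 1.0
    #: per-instrument trait variance sigma_beta^2 (design 1)
    sigma_beta2: float = 0.005
    #: environment main effect (0.1 in design 1; gamma in design 2)
    beta2_env: float = 0.1
    #: interaction effect on the focal variant
    beta3: float = 0.05
    #: G -> E coefficient of the focal variant (design 2 models b/c)
    mediation_coef: float = 0.0
    resid_var: float = 1.0
    #: non-overlap GWAS environment mean multiplier (design 2: 1.5)
    overlap_env_mean_factor: float = 1.0
    center_genotypes: bool = True
    adjust_marginal_for_E: bool = False
    seed: int = 0
    #: design 1 focal main effect; None draws it N(0, sigma_beta^2)
    focal_main_effect: float | None = None
    #: design 2 shared per-variant main effect
    main_effect: float = 0.1
    #: design 2 allele frequency
    maf: float = 0.3
    #: design 2 environment noise variance under mediation
    med_noise_var: float = 0.9975

    @classmethod
    def design1(cls, **overrides) -> "SimulationConfig":
        """The 102-variant no-mediation design with printed defaults."""
        cfg = cls(design="no_mediation")
        return replace(cfg, **overrides)

    @classmethod
    def design2(cls, **overrides) -> "SimulationConfig":
        """The 20-variant mediation panel with printed defaults.

        The GWIS cohort (n2 = 20,000) is always contained in the GWAS
        cohort; non-overlapping GWAS subjects get a 1.5x environment
        mean; residual variance is 10.
        """
        cfg = cls(design="mediation_panel", m=20, n1=20_000, n2=20_000,
                  n0=20_000, beta2_env=1.0, beta3=0.1, mediation_coef=0.05,
                  resid_var=10.0, overlap_env_mean_factor=1.5,
                  center_genotypes=False, mu_E1=1.0, mu_E2=1.0)
        return replace(cfg, **overrides)

    def validate(self) -> None:
        problems = []
        if self.m < 2:
            problems.append("m must be >= 2")
        if not (0 <= self.n0 <= min(self.n1, self.n2)):
            problems.append("need 0 <= n0 <= min(n1, n2)")
        if self.sigma_E1 <= 0 or self.sigma_E2 <= 0:
            problems.append("environment SDs must be positive")
        if self.sigma_beta2 < 0:
            problems.append("sigma_beta2 must be non-negative")
        if self.resid_var <= 0:
            problems.append("resid_var must be positive")
        if self.design not in ("no_mediation", "mediation_panel"):
            problems.append(f"unknown design '{self.design}'")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def focal_index(self) -> int:
        return 0

    @property
    def null_index(self) -> int:
        """Designated null test variant (variant 2 in design 1)."""
        return 1

    @property
    def iv_indices(self) -> np.ndarray:
        """Instrument set: last 100 variants (design 1) / non-focal (design 2)."""
        if self.design == "no_mediation":
            start = 2 if self.m > 2 else 1
            return np.arange(start, self.m)
        return np.arange(1, self.m)

    @property
    def mu_E_gwas(self) -> float:
        """Environment mean over the whole GWAS sample (overlap mixture)."""
        if self.design == "mediation_panel":
            mu_non = self.overlap_env_mean_factor * self.mu_E2
            mu_ovl = self.mu_E2
        else:
            mu_non, mu_ovl = self.mu_E1, self.mu_E2
        return ((self.n1 - self.n0) * mu_non + self.n0 * mu_ovl) / self.n1


@dataclass
class SimulatedData:
    """Individual-level cohorts; the first n0 rows are the shared subjects."""

    G: np.ndarray          # (n1 + n2 - n0) x m standardized genotypes
    E: np.ndarray
    y: np.ndarray
    idx_gwas: np.ndarray
    idx_gwis: np.ndarray
    config: SimulationConfig
    beta1_true: np.ndarray
    freqs: np.ndarray
    model: str | None = None


def _standardize_genotypes(raw: np.ndarray, p: np.ndarray, center: bool) -> np.ndarray:
    scale = np.sqrt(2.0 * p * (1.0 - p))
    g = raw / scale
    if center:
        g = g - (2.0 * p) / scale
    return g


def simulate_no_mediation(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> SimulatedData:
    """Generate the 102-variant no-mediation design."""
    if config.design != "no_mediation":
        raise ValueError("config.design must be 'no_mediation'")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_total = config.n1 + config.n2 - config.n0
    p = rng.uniform(0.05, 0.5, config.m)
    raw = rng.binomial(2, p, size=(n_total, config.m)).astype(np.float64)
    G = _standardize_genotypes(raw, p, config.center_genotypes)

    # rows: [overlap | gwas-only | gwis-only]
    idx_gwas = np.arange(config.n1)
    idx_gwis = np.concatenate([np.arange(config.n0),
                               np.arange(config.n1, n_total)])
    E = np.empty(n_total)
    gwas_only = slice(config.n0, config.n1)
    E[gwas_only] = rng.normal(config.mu_E1, config.sigma_E1, config.n1 - config.n0)
    E[:config.n0] = rng.normal(config.mu_E2, config.sigma_E2, config.n0)
    E[config.n1:] = rng.normal(config.mu_E2, config.sigma_E2, n_total - config.n1)

    beta1 = rng.normal(0.0, math.sqrt(config.sigma_beta2), config.m)
    if config.focal_main_effect is not None:
        beta1[config.focal_index] = config.focal_main_effect
    y = (G @ beta1 + config.beta2_env * E
         + config.beta3 * G[:, config.focal_index] * E
         + rng.normal(0.0, math.sqrt(config.resid_var), n_total))
    return SimulatedData(G, E, y, idx_gwas, idx_gwis, config, beta1, p)


def simulate_mediation_panel(
    config: SimulationConfig,
    model: MediationModel = "a",
    gamma: float | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedData:
    """Generate the 20-variant mediation panel under model a, b or c.

    a: no mediation, no interaction; b: mediation only; c: mediation and
    interaction.  ``gamma`` overrides the environment main effect.
    """
    if config.design != "mediation_panel":
        raise ValueError("config.design must be 'mediation_panel'")
    if model not in ("a", "b", "c"):
        raise ValueError(f"unknown mediation model '{model}'; expected a, b or c")
    config.validate()
    if gamma is None:
        gamma = config.beta2_env
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_total = config.n1 + config.n2 - config.n0
    p = np.full(config.m, config.maf)
    raw = rng.binomial(2, p, size=(n_total, config.m)).astype(np.float64)
    G = _standardize_genotypes(raw, p, config.center_genotypes)

    idx_gwas = np.arange(config.n1)
    idx_gwis = np.concatenate([np.arange(config.n0),
                               np.arange(config.n1, n_total)])
    mu = np.full(n_total, config.mu_E2)
    mu[config.n0:config.n1] = config.overlap_env_mean_factor * config.mu_E2
    if model == "a":
        E = rng.normal(mu, config.sigma_E2)
    else:
        E = (config.mediation_coef * G[:, config.focal_index]
             + rng.normal(mu, math.sqrt(config.med_noise_var)))

    beta1 = np.full(config.m, config.main_effect)
    y = G @ beta1 + gamma * E + rng.normal(
        0.0, math.sqrt(config.resid_var), n_total)
    if model == "c":
        y = y + config.beta3 * G[:, config.focal_index] * E
    return SimulatedData(G, E, y, idx_gwas, idx_gwis, config, beta1, p,
                         model=model)


def mediation_variance_share(mediation_coef: float = 0.05,
                             noise_var: float = 0.9975,
                             var_g: float = 1.0) -> float:
    """Fraction of var(E) attributable to the mediating genotype.

    With a standardized genotype and the default coefficients this is
    0.05^2 / (0.05^2 + 0.9975) = 0.25%.
    """
    g_var = mediation_coef**2 * var_g
    return g_var / (g_var + noise_var)


# ---------------------------------------------------------------------------
# batch least squares


def _batch_marginal_fit(G: np.ndarray, y: np.ndarray,
                        E: np.ndarray | None = None):
    """Per-variant OLS of y on [1, G_j] (plus E when supplied).

    Returns (alpha, se).  Vectorized over variants via cross-product
    moments; identical to column-by-column OLS up to float round-off.
    """
    n, m = G.shape
    if E is None:
        Gc = G - G.mean(axis=0)
        yc = y - y.mean()
        sxx = np.einsum("ij,ij->j", Gc, Gc)
        sxy = Gc.T @ yc
        alpha = sxy / sxx
        rss = float(yc @ yc) - alpha * sxy
        sigma2 = rss / (n - 2)
        return alpha, np.sqrt(sigma2 / sxx)
    # 3-column design [1, G_j, E]
    sG = G.sum(axis=0)
    sG2 = np.einsum("ij,ij->j", G, G)
    sE = E.sum()
    sE2 = float(E @ E)
    sGE = G.T @ E
    sy = y.sum()
    sGy = G.T @ y
    sEy = float(E @ y)
    XtX = np.empty((m, 3, 3))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = sG
    XtX[:, 0, 2] = XtX[:, 2, 0] = sE
    XtX[:, 1, 1] = sG2
    XtX[:, 1, 2] = XtX[:, 2, 1] = sGE
    XtX[:, 2, 2] = sE2
    Xty = np.stack([np.full(m, sy), sGy, np.full(m, sEy)], axis=1)
    coef = np.linalg.solve(XtX, Xty[:, :, None])[:, :, 0]
    rss = float(y @ y) - np.einsum("ij,ij->i", coef, Xty)
    sigma2 = rss / (n - 3)
    inv = np.linalg.inv(XtX)
    se = np.sqrt(sigma2 * inv[:, 1, 1])
    return coef[:, 1], se


def _batch_interaction_fit(G: np.ndarray, E: np.ndarray, y: np.ndarray):
    """Per-variant OLS of y on [1, G_j, E, G_j*E].

    Returns (coef, se) arrays of shape (m, 4) ordered
    (intercept, main, environment, interaction).
    """
    n, m = G.shape
    G2 = G * G
    E2 = E * E
    Ey = E * y
    sG = G.sum(axis=0)
    sG2 = np.einsum("ij,ij->j", G, G)
    sE = E.sum()
    sE2 = float(E @ E)
    sy = y.sum()
    sEy = float(E @ y)
    sGE = G.T @ E
    sG2E = G2.T @ E
    sGE2 = G.T @ E2
    sG2E2 = G2.T @ E2
    sGy = G.T @ y
    sGEy = G.T @ Ey
    XtX = np.empty((m, 4, 4))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = sG
    XtX[:, 0, 2] = XtX[:, 2, 0] = sE
    XtX[:, 0, 3] = XtX[:, 3, 0] = sGE
    XtX[:, 1, 1] = sG2
    XtX[:, 1, 2] = XtX[:, 2, 1] = sGE
    XtX[:, 1, 3] = XtX[:, 3, 1] = sG2E
    XtX[:, 2, 2] = sE2
    XtX[:, 2, 3] = XtX[:, 3, 2] = sGE2
    XtX[:, 3, 3] = sG2E2
    Xty = np.stack([np.full(m, sy), sGy, np.full(m, sEy), sGEy], axis=1)
    coef = np.linalg.solve(XtX, Xty[:, :, None])[:, :, 0]
    rss = float(y @ y) - np.einsum("ij,ij->i", coef, Xty)
    sigma2 = rss / (n - 4)
    inv = np.linalg.inv(XtX)
    se = np.sqrt(sigma2[:, None] * np.diagonal(inv, axis1=1, axis2=2))
    return coef, se


def fit_summary_stats(data: SimulatedData,
                      config: SimulationConfig | None = None) -> HarmonizedPanel:
    """Fit the marginal and interaction models and assemble a panel.

    The marginal model runs on the GWAS sample (optionally adjusted for
    E); the interaction model on the GWIS sample.  Synthetic allele
    bookkeeping is trivial (effect allele A, other allele G).
    """
    cfg = config or data.config
    Gg, yg = data.G[data.idx_gwas], data.y[data.idx_gwas]
    Eg = data.E[data.idx_gwas]
    Gw, yw, Ew = data.G[data.idx_gwis], data.y[data.idx_gwis], data.E[data.idx_gwis]

    alpha, se_alpha = _batch_marginal_fit(
        Gg, yg, Eg if cfg.adjust_marginal_for_E else None)
    coef, se = _batch_interaction_fit(Gw, Ew, yw)

    bad = ~np.isfinite(alpha) | ~np.isfinite(se_alpha) | (se_alpha <= 0) \
        | ~np.isfinite(se).all(axis=1) | (se <= 0).any(axis=1)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} variants with singular fits")

    m = cfg.m
    z_a = alpha / se_alpha
    z_b1 = coef[:, 1] / se[:, 1]
    z_b3 = coef[:, 3] / se[:, 3]
    df = pd.DataFrame({
        "variant_id": [f"snp{j + 1}" for j in range(m)],
        "chrom": "1",
        "pos": 1 + 2_000_000 * np.arange(m),
        "effect_allele": "A",
        "other_allele": "G",
        "alpha_hat": alpha, "se_alpha": se_alpha,
        "p_gwas": stats.chi2.sf(z_a**2, 1),
        "n1": float(len(yg)),
        "eaf_gwas": data.freqs,
        "beta1_hat": coef[:, 1], "se_beta1": se[:, 1],
        "beta2_hat": coef[:, 2], "se_beta2": se[:, 2],
        "beta3_hat": coef[:, 3], "se_beta3": se[:, 3],
        "p_gwis": stats.chi2.sf(z_b1**2, 1),
        "p_inter": stats.chi2.sf(z_b3**2, 1),
        "n2": float(len(yw)),
        "eaf_gwis": data.freqs,
    })
    log = {"input_gwas": m, "input_gwis": m, "removed_singular_fit": int(bad.sum()),
           "retained": int((~bad).sum())}
    return HarmonizedPanel(df[~bad].reset_index(drop=True), log,
                           {"generator": data.config.design})


# ---------------------------------------------------------------------------
# overlap correlation and null summary-stat panels


def shared_residual_variance(config: SimulationConfig, model: str | None = None,
                             gamma: float | None = None) -> float:
    """Residual variance shared by the marginal and interaction fits.

    The noise term plus the polygenic background (all variants other
    than the one being fitted) appear in both models' residuals; the
    environment main effect does not (it is partialled out of the
    interaction model).  Focal interaction/mediation contributions are
    second order and ignored.
    """
    if config.design == "no_mediation":
        background = config.m * config.sigma_beta2
    else:
        background = (config.m - 1) * config.main_effect**2
    return config.resid_var + background


def analytic_overlap_cov(config: SimulationConfig, model: str | None = None,
                         gamma: float | None = None) -> float:
    """Error covariance of (alpha_hat, beta1_hat) induced by shared subjects.

    For standardized genotypes the covariance over n0 shared subjects is
    sigma_shared^2 * n0 / (n1 * n2) on the raw effect scale; dividing by
    the fitted standard errors turns it into the correlation r used by
    the screening statistic.
    """
    sigma_sh2 = shared_residual_variance(config, model, gamma)
    return sigma_sh2 * config.n0 / (config.n1 * config.n2)


def analytic_overlap_corr(config: SimulationConfig, model: str | None = None,
                          gamma: float | None = None) -> float:
    """Design-implied scalar overlap correlation r.

    Divides the shared-subject error covariance by the asymptotic
    standard deviations of the two estimators: for the marginal fit the
    residual includes the environment main effect (unless adjusted), for
    the interaction fit the G/G*E collinearity inflates the main-effect
    variance by (mu_E^2 + sigma_E^2)/sigma_E^2.
    """
    if gamma is None:
        gamma = config.beta2_env
    sigma_sh2 = shared_residual_variance(config, model, gamma)
    cov = sigma_sh2 * config.n0 / (config.n1 * config.n2)
    var_env = 0.0
    if not config.adjust_marginal_for_E:
        # environment variance across the GWAS sample (overlap mixture)
        mu_non = (config.overlap_env_mean_factor * config.mu_E2
                  if config.design == "mediation_panel" else config.mu_E1)
        w = (config.n1 - config.n0) / config.n1
        mean_mix = w * mu_non + (1 - w) * config.mu_E2
        second = (w * (config.sigma_E1**2 + mu_non**2)
                  + (1 - w) * (config.sigma_E2**2 + config.mu_E2**2))
        var_env = gamma**2 * (second - mean_mix**2)
    var_alpha = (sigma_sh2 + var_env) / config.n1
    vif = (config.mu_E2**2 + config.sigma_E2**2) / config.sigma_E2**2
    var_beta1 = sigma_sh2 * vif / config.n2
    return float(np.clip(cov / math.sqrt(var_alpha * var_beta1), -0.999, 0.999))


def overlap_corr_from_cov(cov: float, se_alpha, se_beta1) -> np.ndarray:
    """Per-variant r implied by a raw-scale error covariance."""
    r = cov / (np.asarray(se_alpha, float) * np.asarray(se_beta1, float))
    return np.clip(r, -0.999, 0.999)


def expected_theta_for_config(config: SimulationConfig,
                              include_estimator_cov: bool = True) -> float:
    """Closed-form E[theta-hat] evaluated at a simulation configuration.

    The theoretical expression is derived under a unit residual
    variance, so the per-instrument trait variance is expressed relative
    to the shared residual variance (noise + polygenic background)
    before evaluation.  Overlap-subsample environment moments are the
    GWIS moments, as overlapping subjects draw E from the GWIS
    distribution.  By default the covariance-corrected overlap term is
    used, which Monte Carlo confirms; ``include_estimator_cov=False``
    gives the uncorrected published form (exact when n0 = 0 or the
    overlap environment mean is 0).
    """
    from .mr import expected_theta
    sigma_sh2 = shared_residual_variance(config)
    if config.design == "no_mediation":
        sb2 = config.sigma_beta2
    else:
        sb2 = config.main_effect**2
    return expected_theta(
        sb2 / sigma_sh2, config.n1, config.n2, config.n0,
        mu_E0=config.mu_E2, sigma_E0=config.sigma_E2,
        mu_E2=config.mu_E2, sigma_E2=config.sigma_E2,
        include_estimator_cov=include_estimator_cov)


def simulate_null_sumstat_panel(
    m: int,
    n1: int,
    n2: int,
    overlap_corr: float = 0.0,
    sigma_beta2: float = 0.0,
    theta: float = 1.0,
    seed: int = 0,
    n_chrom: int = 22,
) -> HarmonizedPanel:
    """Draw standardized summary statistics directly from the error model.

    True standardized main effects b_j ~ N(0, sigma_beta2); the GWAS and
    GWIS estimates add correlated noise:

        alpha_hat = theta*b + e0/sqrt(n1),  beta1_hat = b + e1/sqrt(n2),

    with corr(e0, e1) = ``overlap_corr``.  No interaction or mediation
    anywhere — useful for calibration checks, overlap-correlation
    recovery and LDSC null experiments without individual-level data.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, math.sqrt(sigma_beta2), m) if sigma_beta2 > 0 else np.zeros(m)
    cov = np.array([[1.0, overlap_corr], [overlap_corr, 1.0]])
    e = rng.multivariate_normal([0.0, 0.0], cov, size=m)
    alpha = theta * b + e[:, 0] / math.sqrt(n1)
    beta1 = b + e[:, 1] / math.sqrt(n2)
    beta3 = rng.normal(0.0, 1.0, m) / math.sqrt(n2)
    se1 = np.full(m, 1.0 / math.sqrt(n1))
    se2 = np.full(m, 1.0 / math.sqrt(n2))
    df = pd.DataFrame({
        "variant_id": [f"snp{j + 1}" for j in range(m)],
        "chrom": [str(1 + j % n_chrom) for j in range(m)],
        "pos": 1 + 100_000 * (np.arange(m) // n_chrom),
        "effect_allele": "A", "other_allele": "G",
        "alpha_hat": alpha, "se_alpha": se1,
        "p_gwas": stats.chi2.sf((alpha / se1)**2, 1),
        "n1": float(n1), "eaf_gwas": 0.3,
        "beta1_hat": beta1, "se_beta1": se2,
        "beta2_hat": 0.0, "se_beta2": float(1.0 / math.sqrt(n2)),
        "beta3_hat": beta3, "se_beta3": se2,
        "p_gwis": stats.chi2.sf((beta1 / se2)**2, 1),
        "p_inter": stats.chi2.sf((beta3 / se2)**2, 1),
        "n2": float(n2), "eaf_gwis": 0.3,
    })
    return HarmonizedPanel(df, {"input_gwas": m, "input_gwis": m, "retained": m},
                           {"generator": "null_sumstat_panel"})


# ---------------------------------------------------------------------------
# replicate studies


@dataclass
class ReplicateSummary:
    """Aggregated rejection rates and estimator moments over replicates."""

    n_reps: int
    alpha: float
    rates: dict[str, tuple[float, float, float]]  # name -> (rate, lo, hi)
    theta_mean: float
    theta_sd: float
    theta_mc_se: float
    beta3_direct_mean: float
    beta3_direct_mc_se: float
    beta3_mr_mean: float
    beta3_mr_mc_se: float
    n_failed: int = 0
    model: str | None = None

    def table(self) -> pd.DataFrame:
        rows = [{"quantity": k, "value": v, "ci_lo": lo, "ci_hi": hi}
                for k, (v, lo, hi) in self.rates.items()]
        rows += [
            {"quantity": "theta_mean", "value": self.theta_mean,
             "ci_lo": self.theta_mean - 2 * self.theta_mc_se,
             "ci_hi": self.theta_mean + 2 * self.theta_mc_se},
            {"quantity": "beta3_direct_mean", "value": self.beta3_direct_mean,
             "ci_lo": self.beta3_direct_mean - 2 * self.beta3_direct_mc_se,
             "ci_hi": self.beta3_direct_mean + 2 * self.beta3_direct_mc_se},
            {"quantity": "beta3_mr_mean", "value": self.beta3_mr_mean,
             "ci_lo": self.beta3_mr_mean - 2 * self.beta3_mr_mc_se,
             "ci_hi": self.beta3_mr_mean + 2 * self.beta3_mr_mc_se},
        ]
        return pd.DataFrame(rows)


def _rate_ci(hits: np.ndarray, n: int) -> tuple[float, float, float]:
    rate = float(np.mean(hits)) if n else float("nan")
    se = math.sqrt(max(rate * (1 - rate), 0.0) / n) if n else float("nan")
    return rate, max(rate - 1.96 * se, 0.0), min(rate + 1.96 * se, 1.0)


def run_replicates(
    config: SimulationConfig,
    model: MediationModel | None = None,
    gamma: float | None = None,
    n_reps: int = 500,
    alpha: float = 0.05,
    overlap_corr_mode: Literal["analytic", "estimate", "fixed"] = "analytic",
    overlap_corr_value: float = 0.0,
) -> ReplicateSummary:
    """Generate, fit and test ``n_reps`` replicate cohorts.

    Per replicate (seeded ``config.seed + replicate``): simulate the
    cohorts, fit both models per variant, estimate theta by IVW over the
    instrument set, screen every variant with the MR statistic, and
    evaluate T_direct, T_diff and the two-step procedure under the
    Bonferroni scheme (screen at ``alpha``/m, confirm at
    ``alpha``/survivors).  Effects stay on the raw scale: the generator
    standardizes genotypes, which is already the sigma_G = 1 convention
    the theory's closed forms assume.

    Aggregates: power on the focal variant, per-variant type-I on the
    designated null variant at level ``alpha``, family-wise two-step
    null rate, and the means of theta-hat and of both interaction
    estimators (direct beta3-hat, and (alpha - theta*beta1)/mu_E on the
    raw scale with a raw-scale IVW theta).
    """
    config.validate()
    cols = ["theta", "b3_direct", "b3_mr",
            "focal_direct_bonf", "focal_mr_bonf", "focal_two_step",
            "null_direct", "null_mr", "null_diff",
            "null_direct_bonf", "null_mr_bonf", "null_two_step_any"]
    rows: list[dict[str, float]] = []
    n_failed = 0
    mu_e = config.mu_E_gwas
    for rep in range(n_reps):
        rng = np.random.default_rng(config.seed + rep)
        try:
            if config.design == "no_mediation":
                data = simulate_no_mediation(config, rng)
            else:
                data = simulate_mediation_panel(config, model or "a", gamma, rng)
            panel = fit_summary_stats(data, config)
            df = panel.df
            se_a = df["se_alpha"].to_numpy(float)
            se_b = df["se_beta1"].to_numpy(float)

            # genotypes are generated standardized, so the raw effect scale
            # already matches the theory's sigma_G = 1 convention
            if overlap_corr_mode == "analytic":
                cov = analytic_overlap_cov(config, model, gamma)
                r = overlap_corr_from_cov(cov, se_a, se_b)
            elif overlap_corr_mode == "fixed":
                r = np.full(len(df), overlap_corr_value)
            else:
                from .mr import estimate_overlap_corr
                r = np.full(len(df), estimate_overlap_corr(panel))

            iv = config.iv_indices
            effect = ivw_theta(HarmonizedPanel(df.iloc[iv]))

            _, _, t_mr, p_mr = t_mr_gxe_arrays(
                df["alpha_hat"], se_a, df["beta1_hat"], se_b,
                effect.theta_hat, r)
            z3 = df["beta3_hat"].to_numpy() / df["se_beta3"].to_numpy()
            p_direct = stats.chi2.sf(z3**2, 1)
            _, p_diff = t_diff_stat(
                df["alpha_hat"], se_a, df["beta1_hat"], se_b,
                cov=r * se_a * se_b)

            m = len(df)
            bonf = alpha / m
            screen = p_mr < bonf
            n_surv = int(screen.sum())
            stage2 = alpha / n_surv if n_surv else 0.0
            two_pass = screen & (p_direct < stage2)

            foc, nul = config.focal_index, config.null_index
            resid_raw = (df["alpha_hat"].iloc[foc]
                         - effect.theta_hat * df["beta1_hat"].iloc[foc])
            null_set = np.arange(m) != foc
            rows.append({
                "theta": effect.theta_hat,
                "b3_direct": df["beta3_hat"].iloc[foc],
                "b3_mr": resid_raw / mu_e,
                "focal_direct_bonf": p_direct[foc] < bonf,
                "focal_mr_bonf": p_mr[foc] < bonf,
                "focal_two_step": two_pass[foc],
                "null_direct": p_direct[nul] < alpha,
                "null_mr": p_mr[nul] < alpha,
                "null_diff": p_diff[nul] < alpha,
                "null_direct_bonf": bool((p_direct[null_set] < bonf).any()),
                "null_mr_bonf": bool((p_mr[null_set] < bonf).any()),
                "null_two_step_any": bool(two_pass[null_set].any()),
            })
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            warnings.warn(f"replicate {rep} failed: {exc}")
    if not rows:
        raise RuntimeError("every replicate failed")
    out = pd.DataFrame(rows, columns=cols)
    n = len(out)
    rates = {k: _rate_ci(out[k].to_numpy(float), n)
             for k in cols if k not in ("theta", "b3_direct", "b3_mr")}
    return ReplicateSummary(
        n_reps=n, alpha=alpha, rates=rates,
        theta_mean=float(out["theta"].mean()),
        theta_sd=float(out["theta"].std(ddof=1)),
        theta_mc_se=float(out["theta"].std(ddof=1) / math.sqrt(n)),
        beta3_direct_mean=float(out["b3_direct"].mean()),
        beta3_direct_mc_se=float(out["b3_direct"].std(ddof=1) / math.sqrt(n)),
        beta3_mr_mean=float(out["b3_mr"].mean()),
        beta3_mr_mc_se=float(out["b3_mr"].std(ddof=1) / math.sqrt(n)),
        n_failed=n_failed, model=model)
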