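"""Direct, difference and two-step gene-environment interaction tests.

T_direct tests the GWIS interaction coefficient itself; T_diff tests
the marginal-minus-main contrast (equivalent to T_direct when GWAS and
GWIS share the same data); the two-step procedure screens the genome
with the MR-based statistic and confirms survivors with T_direct under
a drastically reduced multiple-testing burden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ld import IndependentLD, PairwiseLD


def t_direct(beta3, se_beta3):
    """Wald test of the GWIS interaction coefficient: beta3^2 / var(beta3).

    Accepts scalars or arrays; returns (statistic, p) with p from the
    upper tail of chi^2_1.
    """
    beta3 = np.asarray(beta3, dtype=float)
    se = np.asarray(se_beta3, dtype=float)
    if np.any(~np.isfinite(beta3)) or np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("t_direct requires finite beta3 and positive se_beta3")
    stat = beta3**2 / se**2
    p = stats.chi2.sf(stat, 1)
    if stat.ndim == 0:
        return float(stat), float(p)
    return stat, p


def t_direct_regression(y, g, e, covariates=None):
    """Fit Y ~ 1 + G + E + G*E (+ covariates) and test the interaction.

    Returns (beta3_hat, se, Wald chi^2_1 statistic, p).  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    if not (len(y) == len(g) == len(e)):
        raise ValueError("y, g and e must have equal lengths")
    cols = {"const": np.ones_like(y), "G": g, "E": e, "GxE": g * e}
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        for k in range(cov.shape[1]):
            cols[f"cov{k}"] = cov[:, k]
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        seen = np.empty((len(y), 0))
        for name in X.columns:
            cand = np.column_stack([seen, X[name]])
            if np.linalg.matrix_rank(cand) == seen.shape[1]:
                bad.append(name)
            else:
                seen = cand
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    b3 = float(fit.params["GxE"])
    se = float(fit.bse["GxE"])
    stat = (b3 / se) ** 2
    return b3, se, stat, float(stats.chi2.sf(stat, 1))


def t_diff(alpha, se_alpha, beta1, se_beta1, overlap_corr: float = 0.0,
           cov: float | np.ndarray | None = None):
    """Difference test of marginal vs main effect: (alpha-beta1)^2/var.

    var(alpha - beta1) = se_alpha^2 + se_beta1^2 - 2 r se_alpha se_beta1,
    or uses an explicit error covariance ``cov`` when supplied (e.g. the
    exact same-sample covariance computed from a joint fit).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta1 = np.asarray(beta1, dtype=float)
    se_a = np.asarray(se_alpha, dtype=float)
    se_b = np.asarray(se_beta1, dtype=float)
    if cov is None:
        cov = overlap_corr * se_a * se_b
    var = se_a**2 + se_b**2 - 2.0 * np.asarray(cov, dtype=float)
    if np.any(var <= 0):
        raise ValueError("non-positive var(alpha - beta1); check the overlap "
                         "correlation / covariance")
    stat = (alpha - beta1) ** 2 / var
    p = stats.chi2.sf(stat, 1)
    if stat.ndim == 0:
        return float(stat), float(p)
    return stat, p


def two_step_stage2_threshold(n_survivors: int, n_exposures: int = 1,
                              alpha: float = 0.05) -> float:
    """Bonferroni threshold for the confirmation stage.

    0.05 / (survivors x exposures): e.g. 17 surviving signals across 4
    environmental factors give 0.05/68 = 7.35e-4.
    """
    if n_survivors <= 0:
        raise ValueError("n_survivors must be positive")
    return alpha / (n_survivors * n_exposures)


def replication_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold for an independent replication set."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def two_step(
    results: pd.DataFrame,
    screen_alpha: float | None = None,
    n_exposures: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-step G×E detection: MR screen, then direct-test confirmation.

    ``results`` must carry ``p_mr`` and either precomputed
    ``t_direct``/``p_direct`` or ``beta3_hat``/``se_beta3`` columns.
    Step 1 keeps variants with p_mr < ``screen_alpha`` (default the
    Bonferroni level ``alpha``/m; use 5e-8 for genome-scale panels).
    Step 2 tests survivors with T_direct at
    ``alpha`` / (n_survivors x n_exposures).  Adds ``screen_pass``,
    ``stage2_threshold`` and ``two_step_pass`` columns.
    """
    df = results.copy()
    m = len(df)
    if screen_alpha is None:
        screen_alpha = alpha / m
    if "p_direct" not in df.columns:
        stat, p = t_direct(df["beta3_hat"], df["se_beta3"])
        df["t_direct"] = stat
        df["p_direct"] = p
    df["screen_pass"] = df["p_mr"] < screen_alpha
    n_surv = int(df["screen_pass"].sum())
    if n_surv == 0:
        df["stage2_threshold"] = np.nan
        df["two_step_pass"] = False
        return df
    thresh = two_step_stage2_threshold(n_surv, n_exposures, alpha)
    df["stage2_threshold"] = thresh
    df["two_step_pass"] = df["screen_pass"] & (df["p_direct"] < thresh)
    return df


@dataclass
class LocusGroup:
    """A 1-Mb region anchored at its most significant variant."""

    lead: str
    chrom: str
    lead_pos: int
    lead_p: float
    members: list[str] = field(default_factory=list)
    signals: list[str] = field(default_factory=list)


def define_loci(
    results: pd.DataFrame,
    window_bp: int = 1_000_000,
    ld: PairwiseLD | None = None,
    r2_max: float = 0.1,
    sig_thresh: float = 5e-8,
    p_col: str = "p_mr",
) -> list[LocusGroup]:
    """Group significant variants into loci and independent signals.

    Iteratively takes the most significant unassigned variant as a
    locus lead and assigns every unassigned significant variant within
    ``window_bp`` on the same chromosome to it; within each locus,
    independent signals are chosen greedily in ascending p order subject
    to pairwise r^2 < ``r2_max``.  The output loci partition the
    significant variants.
    """
    if ld is None:
        ld = IndependentLD()
    sig = results[results[p_col] < sig_thresh].sort_values(
        p_col, kind="stable").reset_index(drop=True)
    unassigned = np.ones(len(sig), dtype=bool)
    chrom = sig["chrom"].astype(str).to_numpy()
    pos = sig["pos"].to_numpy(np.int64)
    vid = sig["variant_id"].to_numpy()
    pvals = sig[p_col].to_numpy(float)
    loci: list[LocusGroup] = []
    while unassigned.any():
        lead_i = int(np.flatnonzero(unassigned)[0])  # smallest p first
        in_locus = unassigned & (chrom == chrom[lead_i]) & (
            np.abs(pos - pos[lead_i]) <= window_bp)
        members = list(np.flatnonzero(in_locus))
        locus = LocusGroup(lead=str(vid[lead_i]), chrom=str(chrom[lead_i]),
                           lead_pos=int(pos[lead_i]), lead_p=float(pvals[lead_i]),
                           members=[str(vid[i]) for i in members])
        for i in members:  # already in ascending p order
            if all(ld.r2(str(vid[i]), s) < r2_max for s in locus.signals):
                locus.signals.append(str(vid[i]))
        loci.append(locus)
        unassigned &= ~in_locus
    return loci


def loci_table(loci: list[LocusGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {"locus": range(1, len(loci) + 1),
         "lead": [l.lead for l in loci],
         "chrom": [l.chrom for l in loci],
         "lead_pos": [l.lead_pos for l in loci],
         "lead_p": [l.lead_p for l in loci],
         "n_members": [len(l.members) for l in loci],
         "n_signals": [len(l.signals) for l in loci],
         "signals": [",".join(l.signals) for l in loci]})


def main_inter_corr(mu_E: float, sigma_E: float) -> float:
    """Correlation between main- and interaction-effect estimators.

    In model (1) the collinearity of G and G*E induces
    corr(beta1_hat, beta3_hat) = -mu_E / sqrt(mu_E^2 + sigma_E^2): zero
    for a centred exposure and approaching -1 as the mean dominates.
    """
    if sigma_E <= 0:
        raise ValueError("sigma_E must be positive")
    return -mu_E / math.sqrt(mu_E**2 + sigma_E**2)
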