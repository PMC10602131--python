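"""LD-score-regression heritability of the interaction+mediation residual.

The screening residual alpha - theta*beta1 isolates the part of the
marginal effect contributed by G×E interaction and mediation through E.
Regressing its chi-square against LD scores,

    E[chi2_j] = (n / M) * h2 * l_j + intercept,

gives a lower bound on the phenotypic variance those mechanisms explain.
Heritability is fitted per chromosome and only non-negative chromosome
estimates are summed, with block-jackknife standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mr import CausalEffect, screen_panel
from .sumstats import HarmonizedPanel


@dataclass
class LDScoreTable:
    """Per-variant LD scores (sum of r^2 with neighbouring variants)."""

    df: pd.DataFrame  # columns: variant_id, chrom, ld_score

    def __post_init__(self):
        need = {"variant_id", "chrom", "ld_score"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"LD score table needs columns {sorted(need)}")
        if self.df["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in LD score table")
        if not np.isfinite(self.df["ld_score"]).all():
            raise ValueError("non-finite LD scores")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read(cls, path, delimiter: str | None = None) -> "LDScoreTable":
        df = pd.read_csv(path, sep=delimiter or r"\s+", engine="python")
        df = df.rename(columns={"SNP": "variant_id", "CHR": "chrom", "L2": "ld_score"})
        df["chrom"] = df["chrom"].astype(str)
        return cls(df[["variant_id", "chrom", "ld_score"]])

    def write(self, path) -> None:
        out = self.df.rename(columns={"variant_id": "SNP", "chrom": "CHR",
                                      "ld_score": "L2"})
        out.to_csv(path, sep="\t", index=False)


@dataclass
class HeritabilityEstimate:
    """Per-chromosome and total heritability from LDSC on residual effects."""

    per_chrom: pd.DataFrame     # chrom, h2, se, intercept, n_snps
    total: float                # sum of non-negative per-chromosome h2
    total_unclipped: float      # plain sum, negatives included
    intercept: float            # genome-wide single-fit intercept
    h2_genomewide: float        # genome-wide single-fit slope
    se_genomewide: float
    n_snps: int
    M: int
    skipped_chroms: list[str] = field(default_factory=list)


def residual_effects(panel: HarmonizedPanel, effect: CausalEffect) -> pd.DataFrame:
    """Per-variant residual alpha - theta*beta1 with its SE and chi-square.

    The chi-square equals the MR screening statistic exactly, so this
    table doubles as the LDSC input and the screen output.
    """
    df = screen_panel(panel, effect)
    out = df[["variant_id", "chrom", "pos", "residual", "se_residual", "t_mr"]]
    return out.rename(columns={"t_mr": "chisq"})


def _wls(x: np.ndarray, z: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of z on [1, x]; returns (slope, intercept)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    zm = (w * z).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (z - zm)).sum() / sxx
    return slope, zm - slope * xm


def _jackknife_se(x: np.ndarray, z: np.ndarray, w: np.ndarray,
                  n_blocks: int) -> float:
    n = len(x)
    n_blocks = max(2, min(n_blocks, n))
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    full, _ = _wls(x, z, w)
    loo = []
    for b in range(n_blocks):
        mask = np.ones(n, dtype=bool)
        mask[edges[b]:edges[b + 1]] = False
        loo.append(_wls(x[mask], z[mask], w[mask])[0])
    loo = np.asarray(loo)
    pseudo = n_blocks * full - (n_blocks - 1) * loo
    return float(pseudo.std(ddof=1) / math.sqrt(n_blocks))


def ldsc_h2(
    residuals: pd.DataFrame,
    ld: LDScoreTable,
    sample_size: float,
    M: int | None = None,
    per_chromosome: bool = True,
    n_blocks: int = 20,
    min_variants: int = 50,
    weights: str = "1/max(l,1)",
) -> HeritabilityEstimate:
    """LD score regression of residual chi-squares on LD scores.

    Parameters
    ----------
    residuals
        Table from :func:`residual_effects` (needs ``variant_id``,
        ``chisq``; chromosome comes from the LD table).
    ld
        LD scores; variants missing from it are dropped.
    sample_size
        Effective n behind the residual effects (the GWAS n).
    M
        Denominator variant count; defaults to the number of regression
        variants.
    per_chromosome
        Fit each chromosome separately and total the non-negative
        estimates (heterogeneity-robust, as opposed to a single
        genome-wide fit which is also reported).
    """
    merged = residuals.merge(ld.df[["variant_id", "chrom", "ld_score"]],
                             on="variant_id", suffixes=("_res", ""))
    if len(merged) < min_variants:
        raise ValueError(f"only {len(merged)} variants have LD scores; "
                         f">= {min_variants} required")
    if M is None:
        M = len(merged)
    chisq = merged["chisq"].to_numpy(float)
    ell = merged["ld_score"].to_numpy(float)
    x = (sample_size / M) * ell
    w = 1.0 / np.maximum(ell, 1.0)

    slope_gw, icpt_gw = _wls(x, chisq, w)
    se_gw = _jackknife_se(x, chisq, w, n_blocks)

    rows = []
    skipped: list[str] = []
    if per_chromosome:
        for chrom, sub in merged.groupby("chrom", sort=False):
            if len(sub) < min_variants:
                warnings.warn(f"chromosome {chrom}: only {len(sub)} variants; "
                              "skipped from the per-chromosome total")
                skipped.append(str(chrom))
                continue
            cz = sub["chisq"].to_numpy(float)
            cl = sub["ld_score"].to_numpy(float)
            # chromosome-specific denominator: the chromosome's share of M,
            # so the per-chromosome slopes sum to the genome-wide h2
            M_c = M * len(sub) / len(merged)
            cx = (sample_size / M_c) * cl
            cw = 1.0 / np.maximum(cl, 1.0)
            slope, icpt = _wls(cx, cz, cw)
            se = _jackknife_se(cx, cz, cw, n_blocks)
            rows.append({"chrom": str(chrom), "h2": slope, "se": se,
                         "intercept": icpt, "n_snps": len(sub)})
    per_chrom = pd.DataFrame(rows, columns=["chrom", "h2", "se", "intercept",
                                            "n_snps"])
    if len(per_chrom):
        total = float(np.clip(per_chrom["h2"], 0.0, None).sum())
        total_unclipped = float(per_chrom["h2"].sum())
    else:
        total = max(slope_gw, 0.0)
        total_unclipped = slope_gw
    return HeritabilityEstimate(
        per_chrom=per_chrom, total=total, total_unclipped=total_unclipped,
        intercept=icpt_gw, h2_genomewide=slope_gw, se_genomewide=se_gw,
        n_snps=len(merged), M=M, skipped_chroms=skipped)


def synth_ld_scores(
    m: int,
    n_chrom: int = 22,
    mean: float = 4.0,
    minimum: float = 1.0,
    shape: float = 2.0,
    seed: int = 0,
    variant_ids: list[str] | None = None,
) -> LDScoreTable:
    """Reproducible shifted-gamma LD scores spread across chromosomes."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    scale = max(mean - minimum, 1e-12) / shape
    scores = minimum + rng.gamma(shape, scale, m)
    ids = variant_ids if variant_ids is not None else [f"snp{j + 1}" for j in range(m)]
    chroms = [str(1 + j % n_chrom) for j in range(m)]
    return LDScoreTable(pd.DataFrame(
        {"variant_id": ids, "chrom": chroms, "ld_score": scores}))


def simulate_ldsc_chisq(
    ld: LDScoreTable,
    h2: float,
    sample_size: float,
    M: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw chi-squares from the LDSC generative model (for recovery tests).

    z_j ~ N(0, 1 + n*h2*l_j/M), chi2_j = z_j^2, so that
    E[chi2_j] = 1 + (n/M)*h2*l_j with unit intercept.
    """
    rng = np.random.default_rng(seed)
    if M is None:
        M = len(ld)
    ell = ld.df["ld_score"].to_numpy(float)
    var = 1.0 + sample_size * h2 * ell / M
    z = rng.normal(0.0, np.sqrt(var))
    return pd.DataFrame({"variant_id": ld.df["variant_id"],
                         "chrom": ld.df["chrom"], "chisq": z**2})
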