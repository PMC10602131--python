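"""Reading, harmonizing and standardizing GWAS / GWIS summary statistics.

A GWAS supplies per-variant *marginal* effects (alpha: trait on genotype,
environment omitted).  A GWIS supplies *main* (beta1), environment (beta2)
and *interaction* (beta3) effects from the model

    Y = beta0 + beta1*G + beta2*E + beta3*G*E + eps.

Downstream MR screening needs the two sources aligned to a shared effect
allele with comparable allele frequencies, which is what
:func:`harmonize` produces.  Every filtering step is counted in the
panel's ``filter_log`` so that input = retained + removed is auditable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})

#: default column names, PLINK-flavoured
DEFAULT_COLUMNS: dict[str, str] = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "FREQ",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
    # optional extra effect columns carried by GWIS outputs
    "beta_env": "BETA_E",
    "se_env": "SE_E",
    "beta_inter": "BETA_INT",
    "se_inter": "SE_INT",
    "p_inter": "P_INT",
}

REQUIRED_ROLES = ("id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se")


class ColumnMapError(ValueError):
    """A required summary-statistic role cannot be mapped to a column."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant's association summary from a single source."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float


@dataclass
class SumstatsTable:
    """Parsed summary statistics plus the per-reason drop counts."""

    df: pd.DataFrame
    parse_log: dict[str, int]
    source: str = ""

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[VariantRecord]:
        for row in self.df.itertuples(index=False):
            yield VariantRecord(
                variant_id=row.variant_id, chrom=row.chrom, pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=float(row.eaf) if "eaf" in self.df.columns else math.nan,
                beta=float(row.beta), se=float(row.se),
                pvalue=float(row.p) if "p" in self.df.columns else math.nan,
                n=float(row.n) if "n" in self.df.columns else math.nan,
            )


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> SumstatsTable:
    """Read a delimited summary-statistics table into a validated frame.

    Parameters
    ----------
    path
        Whitespace- or ``delimiter``-separated text file with a header row.
    column_map
        Mapping from role (``id``, ``chrom``, ``pos``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``p``, ``n`` and the
        optional GWIS roles ``beta_env``/``se_env``/``beta_inter``/
        ``se_inter``/``p_inter``) to the column name in the file.  Roles
        absent from the mapping fall back to :data:`DEFAULT_COLUMNS`.
    delimiter
        Field separator; any whitespace run by default.

    Rows with missing or non-finite effect/SE, non-positive SE, alleles
    outside {A,C,G,T}, frequencies outside (0,1) or p-values outside
    (0,1] are dropped and counted in ``parse_log``.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)

    raw = pd.read_csv(path, sep=delimiter if delimiter else r"\s+", engine="python",
                      dtype=str, comment="#")
    if raw.empty:
        warnings.warn(f"{path}: empty summary-statistics file")
        return SumstatsTable(pd.DataFrame(), {"input": 0}, source=str(path))

    for role in REQUIRED_ROLES:
        if colmap[role] not in raw.columns:
            raise ColumnMapError(
                f"required role '{role}' maps to column '{colmap[role]}' "
                f"which is absent from {path}"
            )

    out = pd.DataFrame(index=raw.index)
    out["variant_id"] = raw[colmap["id"]].astype(str)
    out["chrom"] = raw[colmap["chrom"]].astype(str)
    out["pos"] = pd.to_numeric(raw[colmap["pos"]], errors="coerce")
    out["effect_allele"] = raw[colmap["effect_allele"]].str.upper()
    out["other_allele"] = raw[colmap["other_allele"]].str.upper()
    out["beta"] = pd.to_numeric(raw[colmap["beta"]], errors="coerce")
    out["se"] = pd.to_numeric(raw[colmap["se"]], errors="coerce")
    for role, col in (("eaf", colmap["eaf"]), ("p", colmap["p"]), ("n", colmap["n"]),
                      ("beta_env", colmap["beta_env"]), ("se_env", colmap["se_env"]),
                      ("beta_inter", colmap["beta_inter"]),
                      ("se_inter", colmap["se_inter"]),
                      ("p_inter", colmap["p_inter"])):
        if col in raw.columns:
            out[role] = pd.to_numeric(raw[col], errors="coerce")

    log: dict[str, int] = {"input": len(out)}
    bad_effect = ~np.isfinite(out["beta"]) | ~np.isfinite(out["se"]) | (out["se"] <= 0)
    bad_pos = ~np.isfinite(out["pos"])
    bad_allele = ~(out["effect_allele"].isin(VALID_ALLELES)
                   & out["other_allele"].isin(VALID_ALLELES))
    bad_eaf = pd.Series(False, index=out.index)
    if "eaf" in out.columns:
        bad_eaf = out["eaf"].notna() & ~((out["eaf"] > 0) & (out["eaf"] < 1))
    bad_p = pd.Series(False, index=out.index)
    if "p" in out.columns:
        bad_p = out["p"].notna() & ~((out["p"] > 0) & (out["p"] <= 1))

    log["dropped_effect_or_se"] = int(bad_effect.sum())
    log["dropped_position"] = int((bad_pos & ~bad_effect).sum())
    log["dropped_allele"] = int((bad_allele & ~bad_effect & ~bad_pos).sum())
    log["dropped_eaf"] = int((bad_eaf & ~bad_effect & ~bad_pos & ~bad_allele).sum())
    log["dropped_pvalue"] = int(
        (bad_p & ~bad_eaf & ~bad_effect & ~bad_pos & ~bad_allele).sum())
    keep = ~(bad_effect | bad_pos | bad_allele | bad_eaf | bad_p)
    out = out[keep].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    log["retained"] = len(out)
    return SumstatsTable(out, log, source=str(path))


@dataclass(frozen=True)
class HarmonizedVariant:
    """GWAS marginal and GWIS effects aligned on one effect allele."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    alpha_hat: float
    se_alpha: float
    n1: float
    beta1_hat: float
    se_beta1: float
    beta3_hat: float
    se_beta3: float
    n2: float
    eaf_gwas: float
    eaf_gwis: float
    beta2_hat: float | None = None
    se_beta2: float | None = None
    p_gwas: float | None = None
    p_gwis: float | None = None
    p_inter: float | None = None


@dataclass
class HarmonizedPanel:
    """Analysis-ready paired GWAS/GWIS panel.

    ``df`` carries one row per harmonized variant; ``filter_log`` the
    per-rule removal counts; ``sources`` the provenance of each input.
    """

    df: pd.DataFrame
    filter_log: dict[str, int] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def variants(self) -> Iterator[HarmonizedVariant]:
        cols = self.df.columns
        for row in self.df.itertuples(index=False):
            yield HarmonizedVariant(
                variant_id=row.variant_id, chrom=row.chrom, pos=int(row.pos),
                effect_allele=row.effect_allele,
                alpha_hat=row.alpha_hat, se_alpha=row.se_alpha, n1=row.n1,
                beta1_hat=row.beta1_hat, se_beta1=row.se_beta1,
                beta2_hat=getattr(row, "beta2_hat", None) if "beta2_hat" in cols else None,
                se_beta2=getattr(row, "se_beta2", None) if "se_beta2" in cols else None,
                beta3_hat=row.beta3_hat, se_beta3=row.se_beta3, n2=row.n2,
                eaf_gwas=row.eaf_gwas, eaf_gwis=row.eaf_gwis,
                p_gwas=getattr(row, "p_gwas", None) if "p_gwas" in cols else None,
                p_gwis=getattr(row, "p_gwis", None) if "p_gwis" in cols else None,
                p_inter=getattr(row, "p_inter", None) if "p_inter" in cols else None,
            )

    def _removed(self, rule: str, count: int) -> None:
        self.filter_log[rule] = self.filter_log.get(rule, 0) + int(count)

    def write(self, path, log_path=None) -> None:
        self.df.to_csv(path, sep="\t", index=False)
        if log_path is not None:
            with open(log_path, "w") as fh:
                for key, val in self.filter_log.items():
                    fh.write(f"{key}\t{val}\n")


class EmptyPanelError(RuntimeError):
    """No variants survived harmonization/filtering."""


def _maf(freq: pd.Series | np.ndarray) -> np.ndarray:
    f = np.asarray(freq, dtype=float)
    return np.minimum(f, 1.0 - f)


def harmonize(
    gwas: SumstatsTable | pd.DataFrame,
    gwis: SumstatsTable | pd.DataFrame,
    maf_diff_max: float = 0.15,
    same_pos_maf_max: float = 0.01,
) -> HarmonizedPanel:
    """Match GWAS and GWIS variants and align them to one effect allele.

    Matching is by variant id first, with a chrom:pos fallback for the
    remainder.  When the GWIS effect allele equals the GWAS other allele
    (and vice versa) the GWIS effect signs are flipped and its frequency
    complemented.  Strand-ambiguous pairs ({A,T} or {C,G}), unresolvable
    allele pairs, and pairs whose minor-allele-frequency difference
    exceeds ``maf_diff_max`` are removed.  Position-based matches with
    several variants at the same position must agree in MAF to within
    ``same_pos_maf_max``.
    """
    gdf = (gwas.df if isinstance(gwas, SumstatsTable) else gwas).copy()
    wdf = (gwis.df if isinstance(gwis, SumstatsTable) else gwis).copy()
    if gdf.empty or wdf.empty:
        raise EmptyPanelError("harmonize requires nonempty GWAS and GWIS inputs")

    log: dict[str, int] = {"input_gwas": len(gdf), "input_gwis": len(wdf)}

    gdf = gdf.add_suffix("_gwas").rename(columns={"variant_id_gwas": "variant_id"})
    wdf = wdf.add_suffix("_gwis").rename(columns={"variant_id_gwis": "variant_id"})

    by_id = gdf.merge(wdf, on="variant_id", how="inner")
    # chrom:pos fallback for ids unmatched on either side
    rest_g = gdf[~gdf["variant_id"].isin(by_id["variant_id"])]
    rest_w = wdf[~wdf["variant_id"].isin(by_id["variant_id"])]
    by_pos = rest_g.merge(
        rest_w, left_on=["chrom_gwas", "pos_gwas"], right_on=["chrom_gwis", "pos_gwis"],
        how="inner", suffixes=("", "_w"))
    if len(by_pos):
        by_pos = by_pos.rename(columns={"variant_id": "variant_id"})
        # multiple variants at one position: require near-identical MAF
        sizes = by_pos.groupby(["chrom_gwas", "pos_gwas"])["variant_id"].transform("size")
        maf_d = np.abs(_maf(by_pos["eaf_gwas"]) - _maf(_aligned_eaf(by_pos)))
        ok = (sizes == 1) | (maf_d < same_pos_maf_max)
        log["removed_same_pos_ambiguous"] = int((~ok).sum())
        by_pos = by_pos[ok]
        by_pos = by_pos.drop(columns=[c for c in by_pos.columns if c.endswith("_w")])
    matched = pd.concat([by_id, by_pos], ignore_index=True)
    log["matched"] = len(matched)
    log["unmatched_gwas"] = log["input_gwas"] - len(by_id) - len(by_pos)

    # duplicated ids (multi-allelic remnants): keep the smallest MAF difference
    if matched["variant_id"].duplicated().any():
        maf_d = np.abs(_maf(matched["eaf_gwas"]) - _maf(_aligned_eaf(matched)))
        order = np.argsort(maf_d, kind="stable")
        dedup = matched.iloc[order].drop_duplicates("variant_id", keep="first")
        log["removed_duplicate_id"] = len(matched) - len(dedup)
        matched = dedup.sort_index()

    ea_g = matched["effect_allele_gwas"]
    oa_g = matched["other_allele_gwas"]
    ea_w = matched["effect_allele_gwis"]
    oa_w = matched["other_allele_gwis"]

    ambiguous = (
        ((ea_g == "A") & (oa_g == "T")) | ((ea_g == "T") & (oa_g == "A"))
        | ((ea_g == "C") & (oa_g == "G")) | ((ea_g == "G") & (oa_g == "C"))
    )
    same = (ea_w == ea_g) & (oa_w == oa_g)
    swapped = (ea_w == oa_g) & (oa_w == ea_g)
    mismatch = ~(same | swapped)

    log["removed_strand_ambiguous"] = int((ambiguous & ~mismatch).sum())
    log["removed_allele_mismatch"] = int(mismatch.sum())
    keep = ~ambiguous & ~mismatch
    matched = matched[keep]
    swapped = swapped[keep]

    # flip GWIS effects where its effect allele is the GWAS other allele
    for col in ("beta_gwis", "beta_env_gwis", "beta_inter_gwis"):
        if col in matched.columns:
            matched.loc[swapped, col] = -matched.loc[swapped, col]
    if "eaf_gwis" in matched.columns:
        matched.loc[swapped, "eaf_gwis"] = 1.0 - matched.loc[swapped, "eaf_gwis"]

    if "eaf_gwis" in matched.columns and "eaf_gwas" in matched.columns:
        maf_d = np.abs(_maf(matched["eaf_gwas"]) - _maf(matched["eaf_gwis"]))
        bad = maf_d > maf_diff_max
        log["removed_maf_diff"] = int(np.nansum(bad))
        matched = matched[~np.nan_to_num(bad, nan=False).astype(bool)]
    else:
        log["removed_maf_diff"] = 0

    if matched.empty:
        raise EmptyPanelError("no variants survived harmonization; check allele "
                              "coding and frequency columns")

    panel_df = pd.DataFrame({
        "variant_id": matched["variant_id"].to_numpy(),
        "chrom": matched["chrom_gwas"].to_numpy(),
        "pos": matched["pos_gwas"].to_numpy(),
        "effect_allele": matched["effect_allele_gwas"].to_numpy(),
        "other_allele": matched["other_allele_gwas"].to_numpy(),
        "alpha_hat": matched["beta_gwas"].to_numpy(float),
        "se_alpha": matched["se_gwas"].to_numpy(float),
        "beta1_hat": matched["beta_gwis"].to_numpy(float),
        "se_beta1": matched["se_gwis"].to_numpy(float),
    })
    for src, dst in (("eaf_gwas", "eaf_gwas"), ("eaf_gwis", "eaf_gwis"),
                     ("p_gwas", "p_gwas"), ("p_gwis", "p_gwis"),
                     ("n_gwas", "n1"), ("n_gwis", "n2"),
                     ("beta_env_gwis", "beta2_hat"), ("se_env_gwis", "se_beta2"),
                     ("beta_inter_gwis", "beta3_hat"),
                     ("se_inter_gwis", "se_beta3"),
                     ("p_inter_gwis", "p_inter")):
        if src in matched.columns:
            panel_df[dst] = matched[src].to_numpy(float)
    panel_df = panel_df.reset_index(drop=True)
    log["retained"] = len(panel_df)

    sources = {}
    if isinstance(gwas, SumstatsTable):
        sources["gwas"] = gwas.source
    if isinstance(gwis, SumstatsTable):
        sources["gwis"] = gwis.source
    return HarmonizedPanel(panel_df, log, sources)


def _aligned_eaf(matched: pd.DataFrame) -> pd.Series:
    """GWIS EAF on the GWAS effect allele (complement where swapped)."""
    if "eaf_gwis" not in matched.columns:
        return pd.Series(np.nan, index=matched.index)
    swapped = (matched["effect_allele_gwis"] == matched["other_allele_gwas"]) & (
        matched["other_allele_gwis"] == matched["effect_allele_gwas"])
    eaf = matched["eaf_gwis"].copy()
    eaf[swapped] = 1.0 - eaf[swapped]
    return eaf


def filter_effective_n(
    panel: HarmonizedPanel, min_n_gwas: float = 0, min_n_gwis: float = 0
) -> HarmonizedPanel:
    """Drop variants whose per-variant sample size falls below threshold.

    Removal is strict (< threshold); a variant with n exactly at the
    threshold is retained.
    """
    df = panel.df
    bad = pd.Series(False, index=df.index)
    if "n1" in df.columns and min_n_gwas > 0:
        bad |= df["n1"] < min_n_gwas
    if "n2" in df.columns and min_n_gwis > 0:
        bad |= df["n2"] < min_n_gwis
    out = HarmonizedPanel(df[~bad].reset_index(drop=True), dict(panel.filter_log),
                          dict(panel.sources))
    out._removed("removed_effective_n", int(bad.sum()))
    if out.df.empty:
        warnings.warn("effective-sample-size filter removed every variant")
    return out


def exclude_exposure_loci(
    panel: HarmonizedPanel,
    exposure_hits: Sequence[tuple[str, int]],
    window_bp: int = 500_000,
) -> HarmonizedPanel:
    """Remove variants within ``window_bp`` of any exposure-associated hit.

    ``exposure_hits`` are (chrom, pos) lead positions from a GWAS of the
    environmental exposure itself (their significance filtering happens
    upstream).  Windows are inclusive on both ends, coordinates 1-based.
    """
    df = panel.df
    if len(exposure_hits) == 0:
        return HarmonizedPanel(df.copy(), dict(panel.filter_log), dict(panel.sources))
    bad = np.zeros(len(df), dtype=bool)
    pos = df["pos"].to_numpy(np.int64)
    chrom = df["chrom"].astype(str).to_numpy()
    for hit_chrom, hit_pos in exposure_hits:
        bad |= (chrom == str(hit_chrom)) & (np.abs(pos - int(hit_pos)) <= window_bp)
    out = HarmonizedPanel(df[~bad].reset_index(drop=True), dict(panel.filter_log),
                          dict(panel.sources))
    out._removed("removed_exposure_loci", int(bad.sum()))
    return out


def read_exposure_hits(path, delimiter: str | None = None) -> list[tuple[str, int]]:
    """Read a two-column (CHR, BP) exposure hit list."""
    df = pd.read_csv(path, sep=delimiter or r"\s+", engine="python", header=None,
                     comment="#", dtype=str)
    if len(df.columns) < 2:
        raise ValueError(f"{path}: expected two columns (CHR, BP)")
    if not df.iloc[0, 1].strip().lstrip("-").isdigit():  # header row
        df = df.iloc[1:]
    return [(str(c), int(p)) for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])]


_STD_PAIRS = (("alpha_hat", "se_alpha", "n1"),
              ("beta1_hat", "se_beta1", "n2"),
              ("beta2_hat", "se_beta2", "n2"),
              ("beta3_hat", "se_beta3", "n2"))


def standardize_effects(panel: HarmonizedPanel) -> HarmonizedPanel:
    """Replace each (beta, se) by the z-score-based standardized pair.

    b = z / sqrt(n), se = 1 / sqrt(n) with z = beta/se, putting effects
    in phenotype-SD per genotype-SD units.  The z-statistic of every
    effect (and hence every p-value) is preserved exactly; the original
    scale is kept in ``*_raw`` provenance columns.  Variants without a
    sample size are dropped with a warning.
    """
    df = panel.df.copy()
    have_n = pd.Series(True, index=df.index)
    for _, _, ncol in _STD_PAIRS[:2]:
        if ncol not in df.columns:
            raise ValueError(f"standardize_effects requires the '{ncol}' column")
        have_n &= np.isfinite(df[ncol]) & (df[ncol] > 0)
    if (~have_n).any():
        warnings.warn(f"dropping {int((~have_n).sum())} variants without sample size")
        df = df[have_n]
    for beta_col, se_col, ncol in _STD_PAIRS:
        if beta_col not in df.columns:
            continue
        rawb, rawse = df[beta_col].to_numpy(float), df[se_col].to_numpy(float)
        sqrt_n = np.sqrt(df[ncol].to_numpy(float))
        df[beta_col + "_raw"] = rawb
        df[se_col + "_raw"] = rawse
        df[beta_col] = (rawb / rawse) / sqrt_n
        df[se_col] = 1.0 / sqrt_n
    out = HarmonizedPanel(df.reset_index(drop=True), dict(panel.filter_log),
                          dict(panel.sources))
    out.filter_log["standardized"] = len(df)
    return out


def standardize_variant(v: HarmonizedVariant) -> HarmonizedVariant:
    """Single-variant counterpart of :func:`standardize_effects`."""
    if not (v.n1 and v.n1 > 0 and v.n2 and v.n2 > 0):
        raise ValueError(f"{v.variant_id}: sample size required for standardization")
    s1, s2 = math.sqrt(v.n1), math.sqrt(v.n2)
    kwargs = dict(
        alpha_hat=(v.alpha_hat / v.se_alpha) / s1, se_alpha=1.0 / s1,
        beta1_hat=(v.beta1_hat / v.se_beta1) / s2, se_beta1=1.0 / s2,
        beta3_hat=(v.beta3_hat / v.se_beta3) / s2, se_beta3=1.0 / s2,
    )
    if v.beta2_hat is not None and v.se_beta2 is not None:
        kwargs.update(beta2_hat=(v.beta2_hat / v.se_beta2) / s2, se_beta2=1.0 / s2)
    return replace(v, **kwargs)
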