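import numpy as np
import pandas as pd
import pytest

from mrgxe import HarmonizedPanel


def make_gwas_df(rows):
    """Build a GWAS-style parsed frame from (id, chrom, pos, a1, a2, eaf, beta, se, p, n)."""
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "p", "n"]
    df = pd.DataFrame(rows, columns=cols)
    df["pos"] = df["pos"].astype(np.int64)
    return df


def make_gwis_df(rows):
    """GWIS frame: (id, chrom, pos, a1, a2, eaf, beta, se, p, n, b2, se2, b3, se3)."""
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "p", "n",
            "beta_env", "se_env", "beta_inter", "se_inter"]
    df = pd.DataFrame(rows, columns=cols)
    df["pos"] = df["pos"].astype(np.int64)
    return df


@pytest.fixture
def toy_panel():
    """Five-variant harmonized panel with hand-set effects."""
    df = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(1, 6)],
        "chrom": ["1", "1", "1", "2", "2"],
        "pos": [1_000_000, 1_100_000, 2_600_000, 500_000, 5_000_000],
        "effect_allele": ["A"] * 5,
        "other_allele": ["G"] * 5,
        "alpha_hat": [0.20, 0.10, 0.05, 0.30, -0.10],
        "se_alpha": [0.01, 0.01, 0.01, 0.01, 0.01],
        "p_gwas": [1e-20, 1e-10, 0.2, 1e-30, 1e-12],
        "n1": [100_000.0] * 5,
        "eaf_gwas": [0.3, 0.4, 0.2, 0.25, 0.45],
        "beta1_hat": [0.10, 0.05, 0.02, 0.15, -0.05],
        "se_beta1": [0.012, 0.012, 0.012, 0.012, 0.012],
        "beta3_hat": [0.02, 0.00, 0.01, -0.01, 0.00],
        "se_beta3": [0.01, 0.01, 0.01, 0.01, 0.01],
        "p_gwis": [1e-15, 1e-4, 0.4, 1e-25, 1e-3],
        "n2": [30_000.0] * 5,
        "eaf_gwis": [0.31, 0.41, 0.21, 0.24, 0.46],
    })
    return HarmonizedPanel(df, {"input_gwas": 5, "input_gwis": 5, "retained": 5})


def write_sumstats(path, df, columns=None):
    """Write a parsed frame back to disk under the default column names."""
    rename = {"variant_id": "SNP", "chrom": "CHR", "pos": "BP",
              "effect_allele": "A1", "other_allele": "A2", "eaf": "FREQ",
              "beta": "BETA", "se": "SE", "p": "P", "n": "N",
              "beta_env": "BETA_E", "se_env": "SE_E",
              "beta_inter": "BETA_INT", "se_inter": "SE_INT",
              "p_inter": "P_INT"}
    out = df.rename(columns=rename)
    if columns:
        out = out[columns]
    out.to_csv(path, sep="\t", index=False)
    return path
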