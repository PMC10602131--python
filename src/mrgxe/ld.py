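"""Pairwise linkage-disequilibrium (r²) providers.

Instrument pruning and locus/signal refinement both need the squared
allelic correlation between pairs of variants.  Three sources are
supported: a precomputed pairwise table, a genotype matrix from which
r² is computed on the fly, and the degenerate no-LD provider used for
simulated panels of independent variants.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
import pandas as pd


class PairwiseLD(Protocol):
    """Anything that can report r² for a pair of variant ids."""

    def r2(self, id1: str, id2: str) -> float: ...


class IndependentLD:
    """All pairs unlinked (r² = 0); appropriate for simulated panels."""

    def r2(self, id1: str, id2: str) -> float:
        return 1.0 if id1 == id2 else 0.0


class TableLD:
    """r² looked up in a precomputed pairwise table.

    Parameters
    ----------
    table
        DataFrame with columns ``id1``, ``id2``, ``r2``.  Symmetry is
        enforced; absent pairs default to ``default`` (0 by default).
    """

    def __init__(self, table: pd.DataFrame, default: float = 0.0):
        self._default = float(default)
        self._r2: dict[tuple[str, str], float] = {}
        for id1, id2, r2 in table[["id1", "id2", "r2"]].itertuples(index=False):
            key = (str(id1), str(id2)) if str(id1) <= str(id2) else (str(id2), str(id1))
            self._r2[key] = float(r2)

    def r2(self, id1: str, id2: str) -> float:
        if id1 == id2:
            return 1.0
        key = (id1, id2) if id1 <= id2 else (id2, id1)
        return self._r2.get(key, self._default)

    @classmethod
    def read(cls, path, delimiter: str | None = None, **kwargs) -> "TableLD":
        df = pd.read_csv(path, sep=delimiter or r"\s+", engine="python")
        df.columns = [c.lower() for c in df.columns]
        return cls(df, **kwargs)


class GenotypeLD:
    """r² computed as the squared Pearson correlation of genotype columns.

    Parameters
    ----------
    genotypes
        n_individuals x n_variants array of allele dosages.
    variant_ids
        Column labels aligned with ``genotypes``.
    """

    def __init__(self, genotypes: np.ndarray, variant_ids: list[str]):
        g = np.asarray(genotypes, dtype=float)
        if g.shape[1] != len(variant_ids):
            raise ValueError("genotype columns and variant_ids differ in length")
        self._idx = {v: i for i, v in enumerate(variant_ids)}
        g = g - g.mean(axis=0)
        norms = np.sqrt((g**2).sum(axis=0))
        norms[norms == 0] = np.nan
        self._g = g / norms

    def r2(self, id1: str, id2: str) -> float:
        if id1 == id2:
            return 1.0
        i, j = self._idx[id1], self._idx[id2]
        r = float(self._g[:, i] @ self._g[:, j])
        return r * r
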