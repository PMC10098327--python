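"""Bulk RNA-seq / proteome differential-table filtering and intersection.

Differential genes are defined by |log2FC| >= 1 (inclusive) and raw
p < 0.05 (strict); the multi-omics shared-gene list is the case-insensitive
intersection of the two filtered tables, carrying both tables' statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene", "log2fc", "p")


def _normalize_symbol(g: str) -> str:
    return str(g).strip().lower()


@dataclass
class DiffTable:
    """Gene-level differential statistics from one assay.

    ``table`` must carry columns ``gene``, ``log2fc``, ``p`` with unique gene
    symbols and p-values in [0, 1]; ``source`` names the assay (``rna`` or
    ``protein``).
    """

    table: pd.DataFrame
    source: str = "rna"
    alias_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DiffTable missing required column(s): {', '.join(missing)}")
        self.table = self.table.reset_index(drop=True)
        p = self.table["p"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        keys = self.table["gene"].map(self._key)
        if keys.duplicated().any():
            dup = self.table["gene"][keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate gene symbol in table: {dup}")

    def _key(self, g: str) -> str:
        k = _normalize_symbol(g)
        return _normalize_symbol(self.alias_map.get(k, k))

    @property
    def genes(self) -> pd.Series:
        return self.table["gene"]

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path, source: str = "rna", p_column: str = "p") -> "DiffTable":
        df = pd.read_csv(Path(path), sep="\t")
        if p_column != "p":
            df = df.rename(columns={p_column: "p"})
        return cls(df, source=source)

    def write_tsv(self, path) -> None:
        self.table.to_csv(Path(path), sep="\t", index=False)


def filter_degs(table: DiffTable, min_abs_lfc: float = 1.0, max_p: float = 0.05) -> DiffTable:
    """Keep rows with |log2FC| >= ``min_abs_lfc`` and p < ``max_p``.

    The fold-change bound is inclusive, the p bound strict; input row order
    is preserved.
    """
    df = table.table
    keep = (df["log2fc"].abs() >= min_abs_lfc) & (df["p"] < max_p)
    return DiffTable(df.loc[keep].reset_index(drop=True), source=table.source,
                     alias_map=table.alias_map)


def intersect_degs(a: DiffTable, b: DiffTable) -> pd.DataFrame:
    """Case-insensitive symbol intersection of two (already filtered) tables.

    Returns one row per shared gene, alphabetically ordered, with each
    table's log2FC and p under ``<col>_<source>`` suffixes.
    """
    fa = a.table.assign(_key=a.table["gene"].map(a._key))
    fb = b.table.assign(_key=b.table["gene"].map(b._key))
    sa, sb = a.source, b.source
    if sa == sb:
        sa, sb = f"{sa}_a", f"{sb}_b"
    merged = fa.merge(fb, on="_key", suffixes=(f"_{sa}", f"_{sb}"))
    merged = merged.rename(columns={f"gene_{sa}": "gene"}).drop(columns=[f"gene_{sb}", "_key"])
    cols = ["gene"] + [c for c in merged.columns if c != "gene"]
    return merged[cols].sort_values("gene", key=lambda s: s.str.lower()).reset_index(drop=True)
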