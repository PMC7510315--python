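"""Gene-by-sample expression container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance table with a scale tag.

    ``data`` rows are gene ids, columns sample ids.  ``scale`` records what
    the values are: ``"raw"`` (non-negative normalized abundances, e.g.
    RSEM-style), ``"log"`` (log2(x+1)) or ``"zscore"`` (per-gene standardized).
    Raw matrices must be non-negative; duplicate gene or sample ids are
    rejected.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log", "zscore"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == "raw" and (self.data.to_numpy() < 0).any():
            raise ValueError("raw expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], scale=self.scale)

    def log2p1(self) -> "ExpressionMatrix":
        if self.scale != "raw":
            raise ValueError("log transform expects a raw-scale matrix")
        return ExpressionMatrix(np.log2(self.data + 1.0), scale="log")

    def zscore(self) -> "ExpressionMatrix":
        """Per-gene standardization across samples (constant genes -> 0)."""
        vals = self.data.to_numpy(dtype=float)
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (vals - mean) / sd
        return ExpressionMatrix(
            pd.DataFrame(z, index=self.data.index, columns=self.data.columns),
            scale="zscore",
        )
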