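"""Gene-by-condition expression matrices and their on-disk TSV format.

The canonical file layout is tab-separated: first column holds gene IDs,
the header row holds condition IDs, and cells are non-negative abundances
(RPKM-like semantics; the package treats them as already normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Non-negative gene x condition abundance matrix.

    Parameters
    ----------
    genes
        Unique gene identifiers, one per row.
    conditions
        Condition identifiers, one per column.
    values
        Array of shape ``(len(genes), len(conditions))`` with values >= 0.
    """

    genes: list[str]
    conditions: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.conditions)} conditions"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene IDs")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def condition_column(self, condition: str) -> dict[str, float]:
        """Mapping gene -> expression under one condition."""
        j = self.conditions.index(condition)
        return dict(zip(self.genes, self.values[:, j]))

    def subset_genes(self, keep: list[str]) -> "ExpressionMatrix":
        """Restrict to ``keep`` (order taken from ``keep``); unknown IDs are an error."""
        index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in keep if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in keep]
        return ExpressionMatrix(list(keep), list(self.conditions), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.conditions)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            conditions=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            genes=[str(g) for g in df.index],
            conditions=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )
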