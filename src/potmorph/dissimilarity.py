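"""Labeled symmetric dissimilarity matrices shared across the statistics modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["DissimilarityMatrix"]


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative matrix with zero diagonal over labeled items
    (trials or potters).  Not required to satisfy the triangle inequality —
    the subspace dissimilarity 1 - S in particular need not."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("dissimilarity matrix must have a zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValidationError("dissimilarities must be nonnegative")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        idx = [str(l) for l in self.labels]
        return pd.DataFrame(self.values, index=idx, columns=idx)

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered pair."""
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append((str(self.labels[i]), str(self.labels[j]),
                             self.values[i, j]))
        return pd.DataFrame(rows, columns=["item_a", "item_b", "d"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DissimilarityMatrix":
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))
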