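"""Labeled nonnegative target matrices.

The target of a factorization is an ``m x n`` matrix of nonnegative reals:
features (genes, probes, mutation types) on the rows and samples (tissues,
patients, genomes) on the columns.  Validation is strict by design — NMF on a
matrix with negative entries, NaNs, or empty rows/columns is meaningless, so
those are rejected up front with the offending indices named.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["TargetMatrix"]


def _default_labels(prefix: str, n: int) -> list[str]:
    width = max(1, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


@dataclass
class TargetMatrix:
    """A validated, labeled ``m x n`` nonnegative matrix (features x samples).

    Parameters
    ----------
    values
        2-D array of nonnegative, finite reals.
    row_labels, col_labels
        Unique identifiers per axis.  Generated (``f0001`` / ``s01`` style)
        when omitted.

    Raises
    ------
    ValidationError
        On negative/non-finite entries, all-zero rows or columns, duplicate
        labels, or label/shape mismatch.  Indices in messages are 0-based.
    """

    values: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        m, n = self.values.shape
        if m == 0 or n == 0:
            raise ValidationError(f"empty matrix of shape {self.values.shape}")
        if not self.row_labels:
            self.row_labels = _default_labels("f", m)
        if not self.col_labels:
            self.col_labels = _default_labels("s", n)
        self.row_labels = [str(x) for x in self.row_labels]
        self.col_labels = [str(x) for x in self.col_labels]
        if len(self.row_labels) != m:
            raise ValidationError(f"{len(self.row_labels)} row labels for {m} rows")
        if len(self.col_labels) != n:
            raise ValidationError(f"{len(self.col_labels)} column labels for {n} columns")
        if len(set(self.row_labels)) != m:
            raise ValidationError("row labels are not unique")
        if len(set(self.col_labels)) != n:
            raise ValidationError("column labels are not unique")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(f"non-finite entry at (row {i}, col {j}) [0-based]")
        neg = self.values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative entry {self.values[i, j]} at (row {i}, col {j}) [0-based]"
            )
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            raise ValidationError(f"all-zero rows at indices {zero_rows.tolist()} [0-based]")
        zero_cols = np.flatnonzero(self.values.sum(axis=0) == 0)
        if zero_cols.size:
            raise ValidationError(f"all-zero columns at indices {zero_cols.tolist()} [0-based]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TargetMatrix":
        return cls(df.to_numpy(dtype=float), list(map(str, df.index)), list(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def scaled(self, c: float) -> "TargetMatrix":
        """Return a copy with every entry multiplied by ``c > 0``."""
        if c <= 0:
            raise ValidationError("scale factor must be positive")
        return TargetMatrix(self.values * c, list(self.row_labels), list(self.col_labels))
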