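"""Numeric feature table with explicit missingness.

The package's central container is :class:`FeatureMatrix`: a pandas
DataFrame of real-valued feature columns (missing entries stored as NaN)
plus an optional class-label column that is excluded from imputation and,
by default, from neighbor distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """A numeric table whose missing cells are NaN.

    Parameters
    ----------
    data
        Rows are observations, columns are features (plus at most one label
        column).  Feature columns are coerced to float64; NaN flags a
        missing cell.
    label_column
        Name of the class-label column, or None.  The label column may be
        of any dtype but must be fully observed.
    """

    data: pd.DataFrame
    label_column: str | None = None
    _feature_columns: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("feature matrix must have positive row and column counts")
        if self.label_column is not None:
            if self.label_column not in self.data.columns:
                raise ValueError(f"label column {self.label_column!r} not in table")
            if self.data[self.label_column].isna().any():
                raise ValueError("label column contains missing entries")
        self._feature_columns = [
            c for c in self.data.columns if c != self.label_column
        ]
        if not self._feature_columns:
            raise ValueError("no feature columns")
        # Coerce features to float; non-numeric values raise here.
        self.data = self.data.copy()
        for c in self._feature_columns:
            self.data[c] = pd.to_numeric(self.data[c], errors="raise").astype(float)
        feats = self.data[self._feature_columns].to_numpy()
        if np.isinf(feats).any():
            raise ValueError("feature cells must be finite or missing")
        self.data = self.data.reset_index(drop=True)

    @property
    def feature_columns(self) -> list[str]:
        return list(self._feature_columns)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def feature_values(self) -> np.ndarray:
        """Feature block as a float ndarray (NaN = missing)."""
        return self.data[self._feature_columns].to_numpy(dtype=float)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame over feature columns; True where missing."""
        return self.data[self._feature_columns].isna()

    def n_missing(self) -> int:
        return int(self.missing_mask().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing() == 0

    def labels(self) -> pd.Series:
        if self.label_column is None:
            raise ValueError("matrix has no label column")
        return self.data[self.label_column]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.data.copy(), self.label_column)
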