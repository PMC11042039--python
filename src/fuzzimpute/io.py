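"""CSV readers and writers for feature tables.

Comma-delimited, header row required, "." decimal separator.  The
markers "", "NA" and "?" are recognized as missing by default (UCI
exports conventionally use "?").
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .matrix import FeatureMatrix

__all__ = ["DEFAULT_MISSING_MARKERS", "read_table", "write_table", "write_mask"]

DEFAULT_MISSING_MARKERS = ("", "NA", "?")


def read_table(
    path: str | Path,
    label_column: str | None = None,
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
) -> FeatureMatrix:
    """Read a delimited numeric table into a :class:`FeatureMatrix`."""
    df = pd.read_csv(path, na_values=list(missing_markers), keep_default_na=False, skipinitialspace=True)
    if label_column is not None and label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    return FeatureMatrix(df, label_column)


def write_table(matrix: FeatureMatrix, path: str | Path, missing_marker: str = "") -> None:
    """Write a feature table as CSV, rendering missing cells as ``missing_marker``."""
    matrix.data.to_csv(path, index=False, na_rep=missing_marker)


def write_mask(mask: pd.DataFrame, path: str | Path) -> None:
    """Write a boolean injection mask as a 0/1 CSV."""
    mask.astype(int).to_csv(path, index=False)
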