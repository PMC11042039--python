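"""Conventional missing-value handling: mean/median imputation, listwise deletion."""

from __future__ import annotations

from .matrix import FeatureMatrix

__all__ = ["BASELINE_KINDS", "mean_impute", "median_impute", "listwise_delete"]

BASELINE_KINDS = ("mean", "median", "listwise", "none")


def _column_fill(matrix: FeatureMatrix, statistic: str) -> FeatureMatrix:
    out = matrix.data.copy()
    for col in matrix.feature_columns:
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} has no observed values")
        fill = observed.mean() if statistic == "mean" else observed.median()
        out[col] = out[col].fillna(float(fill))
    return FeatureMatrix(out, matrix.label_column)


def mean_impute(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing cell by its column's arithmetic mean of observed values."""
    return _column_fill(matrix, "mean")


def median_impute(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing cell by its column's median of observed values.

    Even observed counts use the midpoint of the two central order statistics.
    """
    return _column_fill(matrix, "median")


def listwise_delete(matrix: FeatureMatrix) -> FeatureMatrix:
    """Keep only rows with zero missing feature cells, preserving row order."""
    keep = ~matrix.missing_mask().any(axis=1)
    if not keep.any():
        raise ValueError("listwise deletion removed every row")
    return FeatureMatrix(matrix.data.loc[keep].reset_index(drop=True), matrix.label_column)
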