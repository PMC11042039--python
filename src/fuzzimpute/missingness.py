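"""MCAR injection and synthetic classification data.

These utilities make the whole pipeline testable without external
downloads: :func:`generate_synthetic` draws a two-class Gaussian
feature matrix shaped like small clinical classification tables
(hundreds of rows, tens of features, binary label), and
:func:`inject_mcar` blanks an exact fraction of feature cells
completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix

__all__ = [
    "InjectionSpec",
    "SyntheticSpec",
    "inject_mcar",
    "generate_synthetic",
    "restore_truth_error",
]


@dataclass(frozen=True)
class InjectionSpec:
    """Fraction of feature cells to blank, and the RNG seed."""

    proportion: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.proportion < 1:
            raise ValueError("proportion must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and signal strength of a synthetic two-class dataset.

    effect_size is the per-feature shift between the class means, in
    units of the within-class standard deviation (which is 1).
    """

    n_rows: int = 500
    n_features: int = 10
    class_balance: float = 0.5
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_features < 1:
            raise ValueError("n_rows and n_features must be positive")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be strictly between 0 and 1")


def inject_mcar(matrix: FeatureMatrix, spec: InjectionSpec) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Blank exactly round(p * cells) feature cells, uniformly at random.

    The label column is untouched and no row ever loses all of its feature
    values.  Returns the holed matrix and a boolean mask frame (True =
    injected) over the feature columns.  Identical seeds give identical
    masks.
    """
    feats = matrix.feature_columns
    if matrix.data[feats].isna().any().any():
        raise ValueError("input matrix must be complete in its feature columns")
    n, m = matrix.n_rows, len(feats)
    count = round(spec.proportion * n * m)
    if count > n * (m - 1):
        raise ValueError(
            f"cannot blank {count} of {n * m} cells without emptying a row "
            f"(at most {n * (m - 1)} allowed)"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n * m)
    mask = np.zeros((n, m), dtype=bool)
    per_row = np.zeros(n, dtype=int)
    taken = 0
    for cell in order:
        if taken == count:
            break
        i, j = divmod(int(cell), m)
        if per_row[i] == m - 1:  # would empty the row
            continue
        mask[i, j] = True
        per_row[i] += 1
        taken += 1
    out = matrix.data.copy()
    block = out[feats].to_numpy(dtype=float)
    block[mask] = np.nan
    out[feats] = block
    mask_df = pd.DataFrame(mask, columns=feats)
    return FeatureMatrix(out, matrix.label_column), mask_df


def generate_synthetic(spec: SyntheticSpec) -> FeatureMatrix:
    """Two-class Gaussian feature matrix with a binary ``label`` column.

    Class 1 occurs with probability ``class_balance``; each feature is
    N(0, 1) in class 0 and N(effect_size, 1) in class 1, independently.
    All features therefore carry class signal and are correlated through
    the label, which is what lets class-aware neighbors out-predict a
    pooled column mean.
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n_rows) < spec.class_balance).astype(int)
    x = rng.normal(0.0, 1.0, size=(spec.n_rows, spec.n_features))
    x += spec.effect_size * labels[:, None]
    cols = [f"f{j}" for j in range(spec.n_features)]
    df = pd.DataFrame(x, columns=cols)
    df["label"] = labels
    return FeatureMatrix(df, label_column="label")


def restore_truth_error(
    original: FeatureMatrix, imputed: FeatureMatrix, mask: pd.DataFrame
) -> float:
    """Root-mean-square error over the injected cells only."""
    if original.data.shape != imputed.data.shape:
        raise ValueError("matrices must have the same shape")
    m = mask.to_numpy(dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    cols = list(mask.columns)
    truth = original.data[cols].to_numpy(dtype=float)[m]
    filled = imputed.data[cols].to_numpy(dtype=float)[m]
    return float(np.sqrt(np.mean((truth - filled) ** 2)))
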