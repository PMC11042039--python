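"""Nearest-neighbor fuzzy-weighted imputation.

For each missing cell the imputer (i) finds the k complete-case rows
nearest to the target row in Euclidean distance over the shared observed
feature columns, (ii) fits a fuzzy membership function (triangular or
Gaussian) to the k target-column values of those neighbors, (iii) weights
each neighbor value by its own membership, and (iv) imputes the weighted
average.  All imputations read the *original* matrix, so processing order
never matters and imputed values never feed later imputations.

Degenerate situations resolve through a fixed fallback chain:

1. all neighbor values identical            -> impute that value;
2. all-zero triangular weights / sigma == 0 -> arithmetic mean of the
   neighbor values;
3. no eligible candidate row at all         -> column mean of the
   observed values.

Every fallback is logged (logger ``fuzzimpute.imputation``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .matrix import FeatureMatrix
from .membership import (
    DegenerateWeightsError,
    gaussian_membership,
    gaussian_params,
    triangular_membership,
    triangular_params,
    weighted_average,
)

__all__ = [
    "ImputerConfig",
    "NeighborSet",
    "NoCandidatesError",
    "complete_case_distance",
    "select_neighbors",
    "impute_cell",
    "impute_matrix",
]

logger = logging.getLogger(__name__)

MembershipKind = Literal["triangular", "gaussian"]


class NoCandidatesError(ValueError):
    """No eligible complete-case neighbor exists for a cell."""

    def __init__(self, row: int, column: str):
        self.row = row
        self.column = column
        super().__init__(f"no eligible neighbor candidates for cell (row {row}, column {column!r})")


@dataclass(frozen=True)
class ImputerConfig:
    """Settings of the fuzzy-KNN imputer.

    k
        Number of nearest neighbors (>= 1; default 3).
    membership
        "triangular" or "gaussian".
    include_label_in_distance
        Whether the label column participates in neighbor distances
        (off by default).
    distance_columns
        Explicit column subset for distances; None means all feature
        columns except the target column (and the label, unless included).
    """

    k: int = 3
    membership: MembershipKind = "triangular"
    include_label_in_distance: bool = False
    distance_columns: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.membership not in ("triangular", "gaussian"):
            raise ValueError(f"unknown membership kind {self.membership!r}")


@dataclass(frozen=True)
class NeighborSet:
    """Target-column values of the selected neighbors, nearest first."""

    values: tuple[float, ...]
    distances: tuple[float, ...]
    k_requested: int

    def __post_init__(self) -> None:
        if len(self.values) != len(self.distances) or len(self.values) == 0:
            raise ValueError("values and distances must be equal-length and non-empty")
        if len(self.values) > self.k_requested:
            raise ValueError("more neighbors than requested")
        if any(d < 0 for d in self.distances):
            raise ValueError("distances must be non-negative")
        if any(a > b for a, b in zip(self.distances, self.distances[1:])):
            raise ValueError("distances must be sorted non-decreasing")


def complete_case_distance(
    target_row: Sequence[float],
    candidate_row: Sequence[float],
    columns: Sequence[int],
) -> float:
    """Euclidean distance between two rows over the given column indices.

    Both rows must be observed at every compared index; a missing entry is
    a contract violation (callers pre-filter candidates).
    """
    cols = list(columns)
    if not cols:
        raise ValueError("column set must be non-empty")
    t = np.asarray(target_row, dtype=float)[cols]
    c = np.asarray(candidate_row, dtype=float)[cols]
    if np.isnan(t).any() or np.isnan(c).any():
        raise ValueError("missing entry at a compared index")
    return float(np.sqrt(((t - c) ** 2).sum()))


def _distance_column_indices(
    matrix: FeatureMatrix, target_col: str, config: ImputerConfig
) -> list[int]:
    cols = list(matrix.data.columns)
    if config.distance_columns is not None:
        chosen = list(config.distance_columns)
        missing = [c for c in chosen if c not in cols]
        if missing:
            raise ValueError(f"unknown distance columns: {missing}")
    else:
        chosen = [c for c in cols if c != target_col]
        if matrix.label_column is not None and not config.include_label_in_distance:
            chosen = [c for c in chosen if c != matrix.label_column]
    return [cols.index(c) for c in chosen if c != target_col]


def select_neighbors(
    matrix: FeatureMatrix, row: int, target_col: str, config: ImputerConfig
) -> NeighborSet:
    """The (up to) k nearest complete-case values for one missing cell.

    A row is an eligible candidate iff it is observed at the target column
    and at every distance column in use.  Distance columns where the
    *target* row is itself missing are dropped (pairwise-available
    handling).  Ties in distance are broken toward the lower row index.
    """
    grid = matrix.data.to_numpy(dtype=float, na_value=np.nan) if matrix.label_column is None else None
    if grid is None:
        # Label column may be non-numeric; build a float grid with the label
        # encoded only if it participates in distances.
        cols = list(matrix.data.columns)
        grid = np.full(matrix.data.shape, np.nan)
        for j, c in enumerate(cols):
            if c == matrix.label_column:
                if config.include_label_in_distance:
                    grid[:, j] = np.asarray(matrix.data[c], dtype=float)
            else:
                grid[:, j] = matrix.data[c].to_numpy(dtype=float)
    t_idx = list(matrix.data.columns).index(target_col)
    if target_col == matrix.label_column:
        raise ValueError("cannot impute the label column")
    if not np.isnan(grid[row, t_idx]):
        raise ValueError(f"cell (row {row}, column {target_col!r}) is not missing")

    dist_cols = _distance_column_indices(matrix, target_col, config)
    # pairwise-available: keep only distance columns observed in the target row
    dist_cols = [j for j in dist_cols if not np.isnan(grid[row, j])]
    if not dist_cols:
        raise NoCandidatesError(row, target_col)

    observed_target = ~np.isnan(grid[:, t_idx])
    observed_dist = ~np.isnan(grid[:, dist_cols]).any(axis=1)
    eligible = observed_target & observed_dist
    eligible[row] = False
    cand = np.flatnonzero(eligible)
    if cand.size == 0:
        raise NoCandidatesError(row, target_col)

    diffs = grid[np.ix_(cand, dist_cols)] - grid[row, dist_cols]
    dists = np.sqrt((diffs**2).sum(axis=1))
    # stable sort => equal distances resolve to the lower row index
    order = np.argsort(dists, kind="stable")[: config.k]
    chosen = cand[order]
    return NeighborSet(
        values=tuple(float(grid[i, t_idx]) for i in chosen),
        distances=tuple(float(d) for d in dists[order]),
        k_requested=config.k,
    )


def _weighted_impute(values: Sequence[float], kind: MembershipKind) -> float:
    vals = np.asarray(values, dtype=float)
    if np.ptp(vals) == 0:
        return float(vals[0])  # fallback 1: identical neighbor values
    try:
        if kind == "triangular":
            params = triangular_params(vals)
            weights = [triangular_membership(x, params) for x in vals]
        else:
            params = gaussian_params(vals)
            weights = [gaussian_membership(x, params) for x in vals]
        return weighted_average(vals, weights)
    except DegenerateWeightsError:
        logger.info("degenerate weights for neighbor set %s; imputing their mean", list(vals))
        return float(vals.mean())  # fallback 2


def impute_cell(matrix: FeatureMatrix, row: int, col: str, config: ImputerConfig) -> float:
    """Impute one missing cell; total (never raises on degenerate data)."""
    try:
        neighbors = select_neighbors(matrix, row, col, config)
    except NoCandidatesError:
        observed = matrix.data[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        logger.info("no neighbor candidates for (row %d, %r); imputing column mean", row, col)
        return float(observed.mean())  # fallback 3
    return _weighted_impute(neighbors.values, config.membership)


def impute_matrix(matrix: FeatureMatrix, config: ImputerConfig | None = None) -> FeatureMatrix:
    """Impute every missing feature cell against the original matrix.

    Observed cells are never altered and freshly imputed values are never
    reused as neighbors, so the result is independent of processing order.
    Raises if a feature column is entirely missing.
    """
    config = config or ImputerConfig()
    fully_missing = [c for c in matrix.feature_columns if matrix.data[c].isna().all()]
    if fully_missing:
        raise ValueError(f"columns entirely missing, cannot impute: {fully_missing}")
    out = matrix.data.copy()
    mask = matrix.missing_mask()
    n_filled = 0
    for col in matrix.feature_columns:
        for row in np.flatnonzero(mask[col].to_numpy()):
            out.at[int(row), col] = impute_cell(matrix, int(row), col, config)
            n_filled += 1
    logger.debug("imputed %d cells with %s membership, k=%d", n_filled, config.membership, config.k)
    return FeatureMatrix(out, matrix.label_column)
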