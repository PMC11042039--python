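"""Shared fixtures: the hand-calculation grid and a brute-force neighbor oracle."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from fuzzimpute import FeatureMatrix


@pytest.fixture
def worked_grid() -> FeatureMatrix:
    """5x6 grid of the published hand calculation, reconstructed from its
    printed distance arithmetic.

    Row 3 (index 2) is missing column A; its five remaining entries and
    the other rows' entries are read off the four printed Euclidean
    distance computations.  Row 2's column-A value is never printed (that
    row is never among the k=3 nearest), so the 5 here is synthetic
    filler; tests on this grid use k=3 only.  No label column: all five
    non-target columns participate in the distance.
    """
    df = pd.DataFrame(
        {
            "A": [2, 5, np.nan, 7, 1],
            "B": [0, 51, 23, 0, 11],
            "C": [100, 400, 100, 200, 0],
            "D": [0.2, 0.7, 0.9, 0.8, 0.1],
            "E": [2, 0, 3, 5, 4],
            "F": [0, 1, 0, 1, 0],
        }
    )
    return FeatureMatrix(df)


def brute_force_neighbors(
    matrix: FeatureMatrix,
    row: int,
    target_col: str,
    k: int,
    label_column_in_distance: bool = False,
):
    """Independent oracle: every pairwise distance via scalar loops, then sort.

    Returns (values, distances) of the up-to-k nearest candidates, ties
    broken by lower row index, or None when no candidate is eligible.
    """
    df = matrix.data
    cols = [c for c in df.columns if c != target_col]
    if matrix.label_column is not None and not label_column_in_distance:
        cols = [c for c in cols if c != matrix.label_column]
    cols = [c for c in cols if not pd.isna(df.at[row, c])]
    if not cols:
        return None
    scored = []
    for i in range(len(df)):
        if i == row or pd.isna(df.at[i, target_col]):
            continue
        if any(pd.isna(df.at[i, c]) for c in cols):
            continue
        d = math.sqrt(sum((df.at[row, c] - df.at[i, c]) ** 2 for c in cols))
        scored.append((d, i, float(df.at[i, target_col])))
    if not scored:
        return None
    scored.sort(key=lambda t: (t[0], t[1]))
    top = scored[:k]
    return [v for _, _, v in top], [d for d, _, _ in top]
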