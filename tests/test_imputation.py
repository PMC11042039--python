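"""Neighbor selection and end-to-end fuzzy imputation."""

import numpy as np
import pandas as pd
import pytest

from fuzzimpute import (
    FeatureMatrix,
    ImputerConfig,
    NoCandidatesError,
    complete_case_distance,
    impute_cell,
    impute_matrix,
    select_neighbors,
)
from fuzzimpute.imputation import NeighborSet

from conftest import brute_force_neighbors

TRI = ImputerConfig(k=3, membership="triangular")
GAUSS = ImputerConfig(k=3, membership="gaussian")


class TestDistance:
    @pytest.mark.parametrize(
        "other_row, expected",
        [(0, 23.03237), (1, 301.3205), (3, 102.6353), (4, 100.7256)],
    )
    def test_hand_calculation_distances(self, worked_grid, other_row, expected):
        """The four published Euclidean distances from the incomplete row."""
        vals = worked_grid.feature_values()
        d = complete_case_distance(vals[2], vals[other_row], [1, 2, 3, 4, 5])
        assert d == pytest.approx(expected, abs=1e-4)

    def test_zero_to_self_and_pythagoras(self):
        assert complete_case_distance([1.0, 2.0], [1.0, 2.0], [0, 1]) == 0.0
        assert complete_case_distance([0.0, 0.0], [3.0, 4.0], [0, 1]) == 5.0

    def test_symmetry(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 0.0, 2.5]
        assert complete_case_distance(a, b, [0, 1, 2]) == complete_case_distance(b, a, [0, 1, 2])

    def test_empty_columns_rejected(self):
        with pytest.raises(ValueError):
            complete_case_distance([1.0], [2.0], [])

    def test_missing_compared_entry_rejected(self):
        with pytest.raises(ValueError):
            complete_case_distance([np.nan, 1.0], [0.0, 1.0], [0, 1])


class TestSelectNeighbors:
    def test_hand_calculation_neighbors(self, worked_grid):
        """k=3 on the published grid selects values {2, 1, 7}, nearest first."""
        nb = select_neighbors(worked_grid, 2, "A", TRI)
        assert nb.values == (2.0, 1.0, 7.0)
        assert nb.distances == pytest.approx((23.03237, 100.7256, 102.6353), abs=1e-4)

    def test_k_exceeding_pool_returns_all(self, worked_grid):
        nb = select_neighbors(worked_grid, 2, "A", ImputerConfig(k=10))
        assert len(nb.values) == 4
        assert nb.k_requested == 10

    def test_distance_ties_prefer_lower_row_index(self):
        # rows 1 and 3 are both at distance 1 from row 0; only one slot left
        df = pd.DataFrame(
            {"A": [np.nan, 10.0, 20.0, 30.0], "B": [0.0, 1.0, 0.0, 1.0]}
        )
        nb = select_neighbors(FeatureMatrix(df), 0, "A", ImputerConfig(k=2))
        assert nb.values == (20.0, 10.0)  # row 2 at d=0, then row 1 (not row 3)

    def test_no_candidates_raises(self):
        df = pd.DataFrame({"A": [np.nan, np.nan], "B": [1.0, 2.0]})
        with pytest.raises(NoCandidatesError) as exc:
            select_neighbors(FeatureMatrix(df), 0, "A", TRI)
        assert exc.value.row == 0 and exc.value.column == "A"

    def test_candidates_incomplete_at_distance_columns_excluded(self):
        df = pd.DataFrame(
            {
                "A": [np.nan, 5.0, 9.0],
                "B": [1.0, np.nan, 1.0],
                "C": [2.0, 2.0, 2.0],
            }
        )
        nb = select_neighbors(FeatureMatrix(df), 0, "A", TRI)
        assert nb.values == (9.0,)  # row 1 is missing at distance column B

    def test_label_column_excluded_from_distance_by_default(self):
        df = pd.DataFrame(
            {
                "A": [np.nan, 1.0, 2.0],
                "B": [0.0, 0.0, 0.1],
                "y": [0, 1, 0],
            }
        )
        m = FeatureMatrix(df, label_column="y")
        nb = select_neighbors(m, 0, "A", ImputerConfig(k=1))
        assert nb.values == (1.0,)
        nb_lab = select_neighbors(
            m, 0, "A", ImputerConfig(k=1, include_label_in_distance=True)
        )
        assert nb_lab.values == (2.0,)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        """Vectorized selection agrees with an exhaustive scalar scan."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            n, m = int(rng.integers(2, 11)), int(rng.integers(2, 7))
            data = rng.normal(size=(n, m)).round(3)
            holes = rng.random((n, m)) < 0.25
            holes[:, :] &= ~(holes.sum(axis=1) >= m)[:, None]  # keep rows partial
            data[holes] = np.nan
            cols = [f"c{j}" for j in range(m)]
            fm = FeatureMatrix(pd.DataFrame(data, columns=cols))
            k = int(rng.integers(1, 5))
            for i, j in zip(*np.where(np.isnan(data))):
                expected = brute_force_neighbors(fm, int(i), cols[j], k)
                cfg = ImputerConfig(k=k)
                if expected is None:
                    with pytest.raises(NoCandidatesError):
                        select_neighbors(fm, int(i), cols[j], cfg)
                else:
                    nb = select_neighbors(fm, int(i), cols[j], cfg)
                    assert list(nb.values) == pytest.approx(expected[0])
                    assert list(nb.distances) == pytest.approx(expected[1])

    def test_neighbor_set_invariants_enforced(self):
        with pytest.raises(ValueError):
            NeighborSet(values=(1.0,), distances=(1.0, 2.0), k_requested=2)
        with pytest.raises(ValueError):
            NeighborSet(values=(1.0, 2.0), distances=(2.0, 1.0), k_requested=2)
        with pytest.raises(ValueError):
            NeighborSet(values=(1.0, 2.0), distances=(0.0, 1.0), k_requested=1)


class TestImputeCell:
    def test_hand_calculation_triangular(self, worked_grid):
        """Triangular weighting of {2,1,7} imputes exactly 2."""
        assert impute_cell(worked_grid, 2, "A", TRI) == pytest.approx(2.0)

    def test_hand_calculation_gaussian(self, worked_grid):
        """Gaussian weighting imputes ~2.6276 (published rounding: 2.63)."""
        assert impute_cell(worked_grid, 2, "A", GAUSS) == pytest.approx(2.6276, abs=1e-3)

    @pytest.mark.parametrize("membership", ["triangular", "gaussian"])
    def test_k1_returns_nearest_value(self, worked_grid, membership):
        cfg = ImputerConfig(k=1, membership=membership)
        assert impute_cell(worked_grid, 2, "A", cfg) == 2.0

    @pytest.mark.parametrize("membership", ["triangular", "gaussian"])
    def test_identical_neighbor_values_imputed_directly(self, membership):
        df = pd.DataFrame({"A": [3.0, 3.0, 3.0, np.nan], "B": [0.0, 1.0, 2.0, 1.0]})
        cfg = ImputerConfig(k=3, membership=membership)
        assert impute_cell(FeatureMatrix(df), 3, "A", cfg) == 3.0

    def test_two_point_neighbor_set_falls_back_to_mean(self):
        # both values sit at the triangle extremes -> all weights zero
        df = pd.DataFrame({"A": [2.0, 6.0, np.nan], "B": [0.0, 1.0, 0.4]})
        assert impute_cell(FeatureMatrix(df), 2, "A", ImputerConfig(k=2)) == 4.0

    def test_no_candidates_falls_back_to_column_mean(self):
        df = pd.DataFrame({"A": [1.0, 5.0, np.nan], "B": [np.nan, np.nan, 2.0]})
        # both candidate rows are missing at the only distance column
        assert impute_cell(FeatureMatrix(df), 2, "A", TRI) == 3.0

    def test_result_within_neighbor_range(self, worked_grid):
        for cfg in (TRI, GAUSS):
            nb = select_neighbors(worked_grid, 2, "A", cfg)
            out = impute_cell(worked_grid, 2, "A", cfg)
            assert min(nb.values) <= out <= max(nb.values)


class TestImputeMatrix:
    def test_identity_on_complete_data(self):
        df = pd.DataFrame({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        out = impute_matrix(FeatureMatrix(df), TRI)
        pd.testing.assert_frame_equal(out.data, df)

    def test_hand_calculation_grid(self, worked_grid):
        out = impute_matrix(worked_grid, TRI)
        assert out.data.at[2, "A"] == pytest.approx(2.0)
        assert out.is_complete()

    def test_observed_cells_unchanged_and_no_chaining(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(8, 4))
        data[1, 0] = np.nan
        data[5, 2] = np.nan
        data[6, 3] = np.nan
        fm = FeatureMatrix(pd.DataFrame(data, columns=list("ABCD")))
        out = impute_matrix(fm, GAUSS)
        observed = ~np.isnan(data)
        assert np.array_equal(out.feature_values()[observed], data[observed])
        # every filled cell equals a fresh single-cell imputation on the
        # ORIGINAL matrix, so processing order cannot matter
        for i, j in zip(*np.where(np.isnan(data))):
            col = "ABCD"[j]
            assert out.data.at[int(i), col] == impute_cell(fm, int(i), col, GAUSS)

    def test_order_independence_under_row_relabeling(self):
        """Imputing a permuted copy gives the same values per original row."""
        rng = np.random.default_rng(3)
        data = rng.normal(size=(10, 4))
        for i, j in [(0, 1), (3, 2), (7, 0), (9, 3)]:
            data[i, j] = np.nan
        cols = list("ABCD")
        fm = FeatureMatrix(pd.DataFrame(data, columns=cols))
        perm = rng.permutation(10)
        fm_perm = FeatureMatrix(pd.DataFrame(data[perm], columns=cols))
        out = impute_matrix(fm, GAUSS).feature_values()
        out_perm = impute_matrix(fm_perm, GAUSS).feature_values()
        assert np.allclose(out[perm], out_perm)

    def test_entirely_missing_column_rejected(self):
        df = pd.DataFrame({"A": [np.nan, np.nan], "B": [1.0, 2.0]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_matrix(FeatureMatrix(df), TRI)
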