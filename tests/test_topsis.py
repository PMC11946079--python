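"""Virtual-ideal TOPSIS: normalization, ideals, distances, closeness, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fertigation_mcda import (
    DecisionMatrix,
    IndicatorMatrix,
    closeness,
    combined_distances,
    ideal_solutions,
    normalize_matrix,
    rank_alternatives,
    topsis_rank,
    weighted_distance,
)


def decision(values: np.ndarray, weights=None) -> DecisionMatrix:
    Z = pd.DataFrame(values, index=[f"A{i}" for i in range(values.shape[0])])
    if weights is None:
        w = pd.Series(1 / values.shape[1], index=Z.columns)
    else:
        w = pd.Series(weights, index=Z.columns)
    return DecisionMatrix(Z=Z, weights=w)


def classical_topsis_oracle(values: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Textbook TOPSIS closeness, written independently of the package path."""
    zp = values.max(axis=0)
    zm = values.min(axis=0)
    dp = np.sqrt(((values - zp) ** 2 * w).sum(axis=1))
    dm = np.sqrt(((values - zm) ** 2 * w).sum(axis=1))
    return dm / (dp + dm)


class TestNormalization:
    def test_vector_norm(self):
        X = IndicatorMatrix(
            values=pd.DataFrame({"a": [3.0, 4.0]}), directions={"a": "benefit"}
        )
        D = normalize_matrix(X)
        assert np.allclose(D.Z["a"], [0.6, 0.8])

    def test_constant_column(self):
        X = IndicatorMatrix(
            values=pd.DataFrame({"a": [5.0, 5.0, 5.0]}), directions={"a": "benefit"}
        )
        D = normalize_matrix(X)
        assert np.allclose(D.Z["a"], 1 / np.sqrt(3))

    def test_cost_column_inverted_before_normalizing(self):
        X = IndicatorMatrix(
            values=pd.DataFrame({"a": [1.0, 2.0, 3.0]}), directions={"a": "cost"}
        )
        D = normalize_matrix(X)
        inv = np.array([3.0, 2.0, 1.0])
        assert np.allclose(D.Z["a"], inv / np.linalg.norm(inv))

    def test_minmax_scheme(self):
        X = IndicatorMatrix(
            values=pd.DataFrame({"a": [1.0, 2.0, 3.0]}), directions={"a": "benefit"}
        )
        D = normalize_matrix(X, scheme="minmax")
        assert np.allclose(D.Z["a"], [0.0, 0.5, 1.0])


class TestIdealSolutions:
    def test_unit_square(self):
        ideals = ideal_solutions(pd.DataFrame([[1.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(ideals.z_plus, [1, 1])
        assert np.allclose(ideals.z_minus, [0, 0])
        assert np.allclose(ideals.v_plus, [2, 2])
        assert np.allclose(ideals.v_minus, [-1, -1])

    def test_duplicated_row_degenerate(self):
        ideals = ideal_solutions(pd.DataFrame([[0.3, 0.7], [0.3, 0.7]]))
        assert np.allclose(ideals.z_plus, ideals.z_minus)
        assert np.allclose(ideals.v_plus, ideals.v_minus)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_column_scan_and_ordering(self, seed):
        rng = np.random.default_rng(seed)
        Z = pd.DataFrame(rng.uniform(size=(4, 3)))
        ideals = ideal_solutions(Z)
        for j in range(3):
            assert ideals.z_plus.iloc[j] == Z.iloc[:, j].max()
            assert ideals.z_minus.iloc[j] == Z.iloc[:, j].min()
        assert (ideals.v_minus <= ideals.z_minus + 1e-12).all()
        assert (ideals.z_plus <= ideals.v_plus + 1e-12).all()


class TestDistances:
    def test_zero_for_identical(self):
        assert weighted_distance([0.5, 0.5], [0.5, 0.5], [0.3, 0.7]) == 0.0

    def test_forced_arithmetic(self):
        assert weighted_distance([0.0, 0.0], [1.0, 1.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_distance([0.0], [1.0], [-0.1])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        row, ref = rng.normal(size=5), rng.normal(size=5)
        w = rng.uniform(size=5)
        expected = sum(w[j] * (ref[j] - row[j]) ** 2 for j in range(5)) ** 0.5
        assert weighted_distance(row, ref, w) == pytest.approx(expected, rel=1e-12)


class TestCombinedAndCloseness:
    def test_alpha_one_recovers_real_distances(self):
        d = np.array([1.0, 2.0])
        sp, sm = combined_distances(d, 2 * d, 3 * d, 4 * d, alpha=1.0, beta=0.0)
        assert np.allclose(sp, d) and np.allclose(sm, 2 * d)

    def test_beta_share(self):
        sp, _ = combined_distances(np.zeros(1), np.zeros(1), np.array([5.0]), np.zeros(1))
        assert sp[0] == pytest.approx(0.5)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            combined_distances(np.ones(1), np.ones(1), np.ones(1), np.ones(1), 0.0, 0.0)

    def test_closeness_midpoint(self):
        assert closeness(np.array([2.0]), np.array([2.0]))[0] == pytest.approx(0.5)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            closeness(np.zeros(2), np.zeros(2))


class TestVirtualIdealTopsis:
    def test_closed_form_at_ideal_rows(self):
        # rows exactly at Z+ and Z-: C = 11/12 and 1/12 at alpha=.9, beta=.1
        vals = np.array([[0.8, 0.7, 0.9], [0.2, 0.1, 0.3], [0.5, 0.4, 0.6]])
        res = topsis_rank(decision(vals))
        assert res.table.loc["A0", "C"] == pytest.approx(11 / 12, abs=1e-12)
        assert res.table.loc["A1", "C"] == pytest.approx(1 / 12, abs=1e-12)

    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_extreme_row_closeness_sums_to_one(self, seed, alpha, beta):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(size=(5, 4))
        # plant rows exactly at the column-wise extremes
        vals[0] = vals.max(axis=0)
        vals[1] = vals.min(axis=0)
        res = topsis_rank(decision(vals), alpha=alpha, beta=beta)
        assert res.table.loc["A0", "C"] + res.table.loc["A1", "C"] == pytest.approx(
            1.0, abs=1e-9
        )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_classical_limit_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 1.0, size=(9, 5))
        w = rng.uniform(0.1, 1.0, 5)
        w /= w.sum()
        res = topsis_rank(decision(vals, w), alpha=1.0, beta=0.0)
        assert np.allclose(res.table["C"], classical_topsis_oracle(vals, w), atol=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_dominance_preserved(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 1.0, size=(6, 4))
        vals[2] = vals.max(axis=0) + 0.05  # componentwise dominant row
        res = topsis_rank(decision(vals))
        assert res.best == "A2"
        assert (res.table["C"].drop("A2") <= res.table.loc["A2", "C"]).all()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_closeness_never_saturates_with_virtual_blend(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(size=(7, 3))
        res = topsis_rank(decision(vals), alpha=0.9, beta=0.1)
        assert (res.table["C"] > 0).all()
        assert (res.table["C"] < 1).all()


class TestRanking:
    def test_descending_order(self):
        C = pd.Series({"A1": 0.2, "A2": 0.9, "A3": 0.5})
        assert rank_alternatives(C) == ("A2", "A3", "A1")

    def test_ties_keep_input_order(self):
        C = pd.Series({"A1": 0.5, "A2": 0.5, "A3": 0.5})
        assert rank_alternatives(C) == ("A1", "A2", "A3")

    def test_rank_column_consistent(self):
        vals = np.array([[0.9, 0.9], [0.1, 0.1], [0.5, 0.5]])
        res = topsis_rank(decision(vals))
        assert list(res.table.sort_values("rank").index) == list(res.ranking)
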