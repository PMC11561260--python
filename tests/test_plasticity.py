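"""Fate bias, P_hc, ECDF and overlap-matrix behavior against independent
oracles and closed-form expectations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from schybrid.dataio import CellTable, ProbMatrix
from schybrid.plasticity import (PlasticityError, ecdf_curve, fate_bias,
                                 overlap_matrix, phc, phc_table)
from conftest import random_prob_matrix


def brute_force_phc(pa, pb, window):
    """Independent loop-and-count oracle for N/M on a bias window."""
    n = 0
    m = 0
    for a, b in zip(pa, pb):
        if a + b == 0:
            continue
        m += 1
        bias = a / (a + b)
        if window[0] <= bias <= window[1]:
            n += 1
    return n / m


class TestFateBias:
    def _prob(self, rows):
        return ProbMatrix(np.asarray(rows, dtype=float),
                          [f"c{i}" for i in range(len(rows))], ["A", "B"])

    @pytest.mark.parametrize("pa,pb,expected", [
        (0.5, 0.5, 0.5),   # equal commitment = hybrid point
        (0.9, 0.1, 0.9),
        (0.25, 0.75, 0.25),
    ])
    def test_ratio_formula(self, pa, pb, expected):
        res = fate_bias(self._prob([[pa, pb]]), "A", "B")
        assert res.bias[0] == pytest.approx(expected)

    def test_partial_mass_renormalized_within_pair(self):
        prob = ProbMatrix(np.array([[0.2, 0.6, 0.2]]), ["c0"], ["A", "B", "C"])
        res = fate_bias(prob, "A", "B")
        assert res.bias[0] == pytest.approx(0.25)

    def test_signed_formula_available(self):
        res = fate_bias(self._prob([[0.5, 0.5]]), "A", "B", formula="signed")
        assert res.bias[0] == pytest.approx(0.0)

    def test_zero_mass_cell_excluded_from_m(self):
        prob = ProbMatrix(np.array([[0.0, 0.0, 1.0], [0.3, 0.3, 0.4]]),
                          ["dead", "ok"], ["A", "B", "C"])
        res = fate_bias(prob, "A", "B")
        assert list(res.cell_ids) == ["ok"]
        assert list(res.excluded_cells) == ["dead"]
        assert res.m == 1

    def test_unknown_label_fatal(self, tiny_prob):
        with pytest.raises(PlasticityError, match="unknown"):
            fate_bias(tiny_prob, "A", "Z")

    def test_same_type_pair_fatal(self, tiny_prob):
        with pytest.raises(PlasticityError, match="distinct"):
            fate_bias(tiny_prob, "A", "A")

    def test_eligibility_from_cell_table(self, tiny_prob, tiny_cells):
        res = fate_bias(tiny_prob, "A", "B", eligibility=tiny_cells)
        # only cells annotated A or B are eligible (c0, c1, c2)
        assert set(res.cell_ids) == {"c0", "c1", "c2"}

    def test_all_cells_zero_mass_fatal(self):
        prob = ProbMatrix(np.array([[0.0, 0.0, 1.0]]), ["c0"], ["A", "B", "C"])
        with pytest.raises(PlasticityError, match="zero probability"):
            fate_bias(prob, "A", "B")


class TestPhc:
    def _result(self, biases):
        prob = ProbMatrix(
            np.column_stack([biases, 1.0 - np.asarray(biases)]),
            [f"c{i}" for i in range(len(biases))], ["A", "B"])
        return fate_bias(prob, "A", "B")

    def test_all_in_window(self):
        assert phc(self._result([0.5, 0.5, 0.5])) == 1.0

    def test_direct_count(self):
        assert phc(self._result([0.1, 0.45, 0.62, 0.95])) == 0.25

    def test_full_window_is_one(self):
        assert phc(self._result([0.1, 0.9]), window=(0.0, 1.0)) == 1.0

    def test_window_endpoints_inclusive(self):
        assert phc(self._result([0.4, 0.6])) == 1.0

    def test_invalid_window_rejected(self):
        with pytest.raises(PlasticityError, match="window"):
            phc(self._result([0.5]), window=(0.6, 0.4))

    def test_oracle_equivalence_randomized(self):
        """phc matches the brute-force loop-and-count oracle exactly."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            prob = random_prob_matrix(rng, n_cells=200, n_classes=5)
            res = fate_bias(prob, "T0", "T1")
            pa, pb = prob.column("T0"), prob.column("T1")
            for window in [(0.35, 0.65), (0.4, 0.6), (0.45, 0.55)]:
                assert phc(res, window) == brute_force_phc(pa, pb, window)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bias_symmetry_and_swap_invariance(self, seed):
        """bias(A,B) + bias(B,A) = 1; P_hc invariant under pair swap for
        windows symmetric about 0.5."""
        rng = np.random.default_rng(seed)
        prob = random_prob_matrix(rng, n_cells=50, n_classes=3)
        ab = fate_bias(prob, "T0", "T1")
        ba = fate_bias(prob, "T1", "T0")
        np.testing.assert_allclose(ab.bias + ba.bias, 1.0, atol=1e-12)
        for window in [(0.4, 0.6), (0.25, 0.75)]:
            assert phc(ab, window) == phc(ba, window)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nested_window_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        prob = random_prob_matrix(rng, n_cells=80, n_classes=4)
        res = fate_bias(prob, "T0", "T2")
        assert (phc(res, (0.45, 0.55)) <= phc(res, (0.4, 0.6))
                <= phc(res, (0.35, 0.65)))


class TestPhcTable:
    def test_layout_groups_by_windows_and_monotone_columns(self):
        rng = np.random.default_rng(7)
        prob = random_prob_matrix(rng, n_cells=300, n_classes=3)
        cells = CellTable(pd.DataFrame({
            "cell_id": prob.cell_ids,
            "reference_label": rng.choice(["T0", "T1", "T2"], 300),
            "group": np.r_[["ctrl"] * 150, ["mut"] * 150],
        }))
        table = phc_table(prob, [("T0", "T1"), ("T1", "T2")], eligibility=cells)
        assert table.shape == (6, 2)  # 2 groups x 3 windows
        assert list(table.columns) == ["T0_vs_T1", "T1_vs_T2"]
        for group in ("ctrl", "mut"):
            block = table.loc[group]
            wide, mid, narrow = (block.loc["[0.35, 0.65]"],
                                 block.loc["[0.4, 0.6]"],
                                 block.loc["[0.45, 0.55]"])
            assert (narrow <= mid).all() and (mid <= wide).all()

    def test_percent_scale_two_decimals(self):
        prob = ProbMatrix(np.array([[0.5, 0.5], [0.9, 0.1], [0.8, 0.2]]),
                          ["c0", "c1", "c2"], ["A", "B"])
        table = phc_table(prob, [("A", "B")], windows=[(0.4, 0.6)])
        assert table.iloc[0, 0] == pytest.approx(33.33)


class TestECDF:
    def _setup(self, probs_a, labels):
        n = len(probs_a)
        prob = ProbMatrix(np.column_stack([probs_a, 1 - np.asarray(probs_a)]),
                          [f"c{i}" for i in range(n)], ["A", "B"])
        cells = CellTable(pd.DataFrame({
            "cell_id": prob.cell_ids, "reference_label": labels, "group": "g"}))
        return prob, cells

    def test_threshold_fraction_strictly_below(self):
        prob, cells = self._setup([0.2, 0.4, 0.6, 0.8], ["X"] * 4)
        curve = ecdf_curve(prob, "A", cells, threshold=0.5)
        assert curve.threshold_fraction["X"] == 0.5

    def test_probability_one_everywhere_gives_zero_fraction(self):
        prob, cells = self._setup([1.0, 1.0], ["X", "X"])
        curve = ecdf_curve(prob, "A", cells, threshold=0.5)
        assert curve.threshold_fraction["X"] == 0.0

    def test_cdf_reaches_one_and_is_monotone(self):
        prob, cells = self._setup([0.3, 0.9, 0.1, 0.5], ["X", "X", "Y", "Y"])
        curve = ecdf_curve(prob, "A", cells)
        for group in ("X", "Y"):
            cum = curve.cumulative[group]
            assert cum[-1] == 1.0
            assert (np.diff(cum) >= 0).all()
            assert (np.diff(curve.values[group]) >= 0).all()

    def test_empty_group_omitted_with_warning(self):
        prob, cells = self._setup([0.3, 0.9], ["X", "X"])
        extra = CellTable(pd.DataFrame({
            "cell_id": ["c0", "c1", "ghost"],
            "reference_label": ["X", "X", "Y"], "group": "g"}))
        with pytest.warns(UserWarning, match="'Y'"):
            curve = ecdf_curve(prob, "A", extra)
        assert set(curve.values) == {"X"}


class TestOverlapMatrix:
    def _cells(self, labels):
        return CellTable(pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(len(labels))],
            "reference_label": labels, "group": "g"}))

    def test_direct_count_example(self):
        om = overlap_matrix(self._cells(["A", "A", "B"]), ["A", "B", "B"])
        assert om.matrix.loc["A"].tolist() == [0.5, 0.5]
        assert om.matrix.loc["B"].tolist() == [0.0, 1.0]

    def test_identity_when_predictions_match(self):
        om = overlap_matrix(self._cells(["A", "B", "C"]), ["A", "B", "C"])
        np.testing.assert_array_equal(om.matrix.to_numpy(), np.eye(3))
        assert om.flagged_types == []

    def test_rows_always_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            labels = rng.choice(list("ABCD"), 60)
            pred = rng.choice(list("ABCD"), 60)
            om = overlap_matrix(self._cells(labels), pred)
            np.testing.assert_allclose(om.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_low_diagonal_rows_flagged(self):
        om = overlap_matrix(self._cells(["A"] * 10 + ["B"] * 10),
                            ["A"] * 7 + ["B"] * 3 + ["B"] * 10)
        assert om.flagged_types == ["A"]

    def test_disjoint_label_sets_fatal(self):
        with pytest.raises(PlasticityError, match="disjoint"):
            overlap_matrix(self._cells(["A", "B"]), ["X", "Y"])
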