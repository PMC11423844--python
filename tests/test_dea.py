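"""Envelopment LP contracts, geometric oracle equivalence, DEA axioms."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from deapanel.dea import (
    DeaProblem,
    farrell_output_distance,
    score_year,
    solve_problem,
)
from deapanel.oracles import hull_oracle_1in_1out, vertex_oracle
from deapanel.synthetic import INPUT_COLS, OUTPUT_COLS

from conftest import random_dea_instance


class TestFarrellDistance:
    def test_single_dmu_is_efficient(self):
        prob = DeaProblem(X=[[2.0]], Y=[[3.0]])
        s = farrell_output_distance(prob, 0)
        assert s.theta == pytest.approx(1.0, abs=1e-9)
        assert s.efficiency == pytest.approx(1.0, abs=1e-9)

    def test_dominated_dmu_output_doubling(self):
        # B produces half of A's output from the same input: theta_B = 2
        prob = DeaProblem(X=[[1.0], [1.0]], Y=[[2.0], [1.0]])
        assert farrell_output_distance(prob, 1).theta == pytest.approx(2.0, abs=1e-8)
        assert farrell_output_distance(prob, 1).efficiency == pytest.approx(0.5, abs=1e-8)

    def test_vrs_lambda_sums_to_one(self):
        X, Y = random_dea_instance(2, n=8)
        prob = DeaProblem(X=X, Y=Y)
        for s in solve_problem(prob):
            assert s.lam.sum() == pytest.approx(1.0, abs=1e-8)
            assert s.efficiency * s.theta == pytest.approx(1.0, abs=1e-9)

    def test_invalid_problems_rejected(self):
        with pytest.raises(ValueError):
            DeaProblem(X=[[1.0]], Y=[[0.0]])  # all-zero output row
        with pytest.raises(ValueError):
            DeaProblem(X=[[0.0], [0.0]], Y=[[1.0], [1.0]])  # all-zero input col
        with pytest.raises(ValueError):
            DeaProblem(X=[[-1.0]], Y=[[1.0]])


class TestOracleEquivalence:
    def test_hull_oracle_duplicate_x(self):
        theta = hull_oracle_1in_1out(np.array([1.0, 1.0]), np.array([2.0, 1.0]))
        assert theta == pytest.approx([1.0, 2.0])

    def test_hull_oracle_collinear_frontier(self):
        theta = hull_oracle_1in_1out(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])
        )
        assert theta == pytest.approx([1.0, 1.0, 1.0])

    def test_hull_oracle_toy_year(self):
        # chord from (2,3) to (4,4) evaluated at x=3 gives frontier 3.5
        x = np.array([1.0, 2.0, 4.0, 3.0])
        y = np.array([1.0, 3.0, 4.0, 2.0])
        prob = DeaProblem(X=x, Y=y)
        theta = farrell_output_distance(prob, 3).theta
        assert theta == pytest.approx(3.5 / 2.0, abs=1e-8)
        assert theta == pytest.approx(hull_oracle_1in_1out(x, y)[3], abs=1e-8)

    def test_lp_matches_hull_oracle_30_random_points(self):
        r = np.random.default_rng(3)
        x = r.uniform(0.5, 5.0, 30)
        y = r.uniform(0.5, 5.0, 30)
        prob = DeaProblem(X=x, Y=y)
        lp = np.array([s.theta for s in solve_problem(prob)])
        assert np.abs(lp - hull_oracle_1in_1out(x, y)).max() < 1e-6

    def test_lp_matches_vertex_oracle_12_dmus(self):
        X, Y = random_dea_instance(7, n=12, p=2, q=2)
        prob = DeaProblem(X=X, Y=Y)
        for i in range(12):
            lp = farrell_output_distance(prob, i).theta
            assert lp == pytest.approx(vertex_oracle(X, Y, i), abs=1e-6)


class TestDeaAxioms:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_units_invariance(self, seed):
        X, Y = random_dea_instance(seed, n=8)
        r = np.random.default_rng(seed + 1)
        cx = r.uniform(0.1, 10.0, X.shape[1])
        cy = r.uniform(0.1, 10.0, Y.shape[1])
        eff1 = [s.efficiency for s in solve_problem(DeaProblem(X=X, Y=Y))]
        eff2 = [s.efficiency for s in solve_problem(DeaProblem(X=X * cx, Y=Y * cy))]
        assert np.abs(np.array(eff1) - np.array(eff2)).max() < 1e-7

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_dominance_monotonicity_in_outputs(self, seed):
        X, Y = random_dea_instance(seed, n=8)
        prob = DeaProblem(X=X, Y=Y)
        before = farrell_output_distance(prob, 0).efficiency
        Y2 = Y.copy()
        Y2[0, 0] *= 1.5
        after = farrell_output_distance(DeaProblem(X=X, Y=Y2), 0).efficiency
        assert after >= before - 1e-7

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_vrs_envelops_tighter_than_crs(self, seed):
        X, Y = random_dea_instance(seed, n=8)
        vrs = solve_problem(DeaProblem(X=X, Y=Y, returns_to_scale="vrs"))
        crs = solve_problem(DeaProblem(X=X, Y=Y, returns_to_scale="crs"))
        for v, c in zip(vrs, crs):
            assert v.efficiency >= c.efficiency - 1e-8
            assert 0.0 < v.efficiency <= 1.0
            assert v.theta >= 1.0


class TestScoreYear:
    def test_identical_dmus_all_efficient(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"jurisdiction_id": list("abcd"), "x": 2.0, "y": 3.0}
        )
        out = score_year(frame, ["x"], ["y"], year=2009)
        assert np.allclose(out.efficiency, 1.0)

    def test_frontier_never_empty(self, noisefree_small_panel):
        _, panel, _ = noisefree_small_panel
        out = score_year(panel, INPUT_COLS, OUTPUT_COLS, year=2009)
        assert np.isclose(out.efficiency.max(), 1.0, atol=1e-7)

    def test_recovery_of_true_ranking(self, noisefree_small_panel):
        _, panel, truth = noisefree_small_panel
        out = score_year(panel, INPUT_COLS, OUTPUT_COLS, year=2009)
        rho = spearmanr(truth.true_efficiency, out.efficiency).statistic
        assert rho >= 0.8

    def test_zero_input_column_dropped_with_warning(self, caplog):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "jurisdiction_id": list("abc"),
                "x1": [1.0, 2.0, 3.0],
                "x2": [0.0, 0.0, 0.0],
                "y": [1.0, 2.0, 2.5],
            }
        )
        with caplog.at_level(logging.WARNING, logger="deapanel.dea"):
            out = score_year(frame, ["x1", "x2"], ["y"], year=2009)
        assert "x2" in caplog.text
        assert len(out) == 3

    def test_too_few_dmus_rejected(self):
        import pandas as pd

        frame = pd.DataFrame({"jurisdiction_id": ["a"], "x": [1.0], "y": [1.0]})
        with pytest.raises(ValueError, match="at least 2"):
            score_year(frame, ["x"], ["y"])

    def test_missing_values_named(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "jurisdiction_id": list("abc"),
                "x": [1.0, np.nan, 3.0],
                "y": [1.0, 2.0, 2.5],
            }
        )
        with pytest.raises(ValueError, match="missing values in rows \\[1\\]"):
            score_year(frame, ["x"], ["y"])
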