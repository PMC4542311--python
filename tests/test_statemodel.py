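"""Residual model, differential selection, and lineage-score trajectory."""

import numpy as np
import pandas as pd
import pytest

from scmethdyn.regionagg import RegionSetMatrix
from scmethdyn.simdata import simulate_regionset_matrix
from scmethdyn.statemodel import (
    control_reference,
    fit_residual_table,
    fit_residuals,
    lineage_scores,
    normalize_to_control,
    run_trajectory,
    select_differential,
)


def _matrix(values: dict, index) -> RegionSetMatrix:
    v = pd.DataFrame(values, index=index)
    n = pd.DataFrame(100, index=v.index, columns=v.columns)
    return RegionSetMatrix(values=v, n_measurements=n)


class TestControlReference:
    def test_mean_of_controls(self):
        m = _matrix({"a": [0.4, 0.6, 0.9]}, ["c1", "c2", "t1"])
        ref = control_reference(m, ["c1", "c2"])
        assert ref["a"] == pytest.approx(0.5)

    def test_missing_control_skipped(self):
        m = _matrix({"a": [np.nan, 0.8, 0.1]}, ["c1", "c2", "t1"])
        assert control_reference(m, ["c1", "c2"])["a"] == pytest.approx(0.8)

    def test_all_controls_missing_drops_set(self):
        m = _matrix({"a": [np.nan, np.nan, 0.1], "b": [0.2, 0.4, 0.5]}, ["c1", "c2", "t1"])
        ref = control_reference(m, ["c1", "c2"])
        assert "a" not in ref.index and "b" in ref.index

    def test_empty_controls_error(self):
        m = _matrix({"a": [0.1]}, ["c1"])
        with pytest.raises(ValueError):
            control_reference(m, [])


class TestNormalize:
    def test_subtraction_and_missing_propagation(self):
        m = _matrix({"a": [0.3, np.nan], "b": [0.9, 0.7]}, ["s1", "s2"])
        ref = pd.Series({"a": 0.5, "b": 0.7})
        diff = normalize_to_control(m, ref)
        assert diff.loc["s1", "a"] == pytest.approx(-0.2)
        assert np.isnan(diff.loc["s2", "a"])
        assert diff.loc["s2", "b"] == pytest.approx(0.0)


class TestFitResiduals:
    def test_exact_linear_data(self, rng):
        """diff built exactly as 0.1 - 0.5*ref + 0.01*cpg gives zero residuals."""
        sets = [f"s{i}" for i in range(5)]
        ref = pd.Series(rng.uniform(0.2, 0.8, 5), index=sets)
        cpg = pd.Series(rng.uniform(1, 10, 5), index=sets)
        diff = 0.1 - 0.5 * ref + 0.01 * cpg
        residuals, coef = fit_residuals(diff, ref, cpg)
        assert np.abs(residuals).max() < 1e-10
        assert coef == pytest.approx([0.1, -0.5, 0.01])

    def test_zero_diff(self, rng):
        sets = [f"s{i}" for i in range(6)]
        ref = pd.Series(rng.uniform(0, 1, 6), index=sets)
        cpg = pd.Series(rng.uniform(0, 10, 6), index=sets)
        residuals, coef = fit_residuals(pd.Series(0.0, index=sets), ref, cpg)
        assert np.abs(residuals).max() < 1e-12
        assert np.abs(coef).max() < 1e-12

    def test_matches_normal_equations_oracle(self, rng):
        """Randomized 50-set instances agree with a brute-force solve."""
        for _ in range(10):
            sets = [f"s{i}" for i in range(50)]
            ref = pd.Series(rng.uniform(0, 1, 50), index=sets)
            cpg = pd.Series(rng.uniform(0, 15, 50), index=sets)
            diff = pd.Series(rng.normal(0, 0.1, 50), index=sets)
            residuals, _ = fit_residuals(diff, ref, cpg)
            X = np.column_stack([np.ones(50), ref, cpg])
            beta = np.linalg.solve(X.T @ X, X.T @ diff.to_numpy())
            expected = diff.to_numpy() - X @ beta
            assert np.abs(residuals.to_numpy() - expected).max() < 1e-8

    def test_residuals_centered_and_orthogonal(self, rng):
        sets = [f"s{i}" for i in range(40)]
        ref = pd.Series(rng.uniform(0, 1, 40), index=sets)
        cpg = pd.Series(rng.uniform(0, 15, 40), index=sets)
        diff = pd.Series(rng.normal(0, 0.1, 40), index=sets)
        residuals, _ = fit_residuals(diff, ref, cpg)
        r = residuals.to_numpy()
        assert abs(r.mean()) < 1e-10
        assert abs(r @ ref.to_numpy()) < 1e-8
        assert abs(r @ cpg.to_numpy()) < 1e-8

    def test_too_few_sets_error(self):
        idx = ["a", "b"]
        s = pd.Series([0.1, 0.2], index=idx)
        with pytest.raises(ValueError, match=">= 3"):
            fit_residuals(s, s, s)

    def test_collinear_design_named(self):
        idx = [f"s{i}" for i in range(5)]
        diff = pd.Series(np.arange(5.0), index=idx)
        const_ref = pd.Series(0.5, index=idx)
        cpg = pd.Series(np.arange(5.0), index=idx)
        with pytest.raises(ValueError, match="control_meth"):
            fit_residuals(diff, const_ref, cpg)
        with pytest.raises(ValueError, match="cpg_percent"):
            fit_residuals(diff, cpg, const_ref)

    def test_incomplete_sets_excluded_from_fit(self, rng):
        sets = [f"s{i}" for i in range(10)]
        ref = pd.Series(rng.uniform(0, 1, 10), index=sets)
        cpg = pd.Series(rng.uniform(0, 10, 10), index=sets)
        diff = pd.Series(rng.normal(0, 0.1, 10), index=sets)
        diff.iloc[3] = np.nan
        residuals, _ = fit_residuals(diff, ref, cpg)
        assert np.isnan(residuals.iloc[3])
        assert residuals.notna().sum() == 9


class TestSelectDifferential:
    def _residuals(self, control_rows, treated_rows, columns):
        index = [f"c{i}" for i in range(len(control_rows))] + [
            f"t{i}" for i in range(len(treated_rows))
        ]
        return (
            pd.DataFrame(control_rows + treated_rows, index=index, columns=columns),
            [f"t{i}" for i in range(len(treated_rows))],
            [f"c{i}" for i in range(len(control_rows))],
        )

    def test_welch_oracle_example(self):
        """Frozen Welch computation: t = 34.641..., df = 6, p = 3.855e-8."""
        control = [-0.01, 0.0, 0.01, 0.0]
        treated = [0.19, 0.21, 0.20, 0.20]
        residuals, t_ids, c_ids = self._residuals(
            [[v] for v in control], [[v] for v in treated], ["setA"]
        )
        sel = select_differential(residuals, t_ids, c_ids)
        (name, t, p) = sel.positive_sets[0]
        assert name == "setA"
        assert t == pytest.approx(34.6410161514, rel=1e-9)
        assert p == pytest.approx(3.855438394138e-08, rel=1e-6)
        assert sel.negative_sets == []

    def test_identical_distributions_select_nothing(self, rng):
        data = rng.normal(0, 0.1, size=(8, 30))
        residuals = pd.DataFrame(
            np.vstack([data, data]),
            index=[f"c{i}" for i in range(8)] + [f"t{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(30)],
        )
        sel = select_differential(residuals, [f"t{i}" for i in range(8)], [f"c{i}" for i in range(8)])
        assert sel.positive_sets == [] and sel.negative_sets == []

    def test_cap_at_max_sets(self, rng):
        """30 strongly positive sets: exactly 20 retained."""
        cols = [f"s{i:02d}" for i in range(30)]
        control = rng.normal(0, 0.01, size=(6, 30))
        treated = rng.normal(0.5, 0.01, size=(6, 30))
        residuals, t_ids, c_ids = self._residuals(list(control), list(treated), cols)
        sel = select_differential(residuals, t_ids, c_ids)
        assert len(sel.positive_sets) == 20
        assert all(p < 0.01 for _, _, p in sel.positive_sets)

    def test_alpha_extremes(self, rng):
        cols = [f"s{i}" for i in range(10)]
        control = rng.normal(0, 0.05, size=(5, 10))
        treated = rng.normal(0.4, 0.05, size=(5, 10))
        residuals, t_ids, c_ids = self._residuals(list(control), list(treated), cols)
        none = select_differential(residuals, t_ids, c_ids, alpha=0.0)
        assert none.positive_sets == [] and none.negative_sets == []
        everything = select_differential(residuals, t_ids, c_ids, alpha=1.0, max_sets=20)
        assert len(everything.positive_sets) + len(everything.negative_sets) == 10

    def test_untestable_sets_skipped(self):
        residuals = pd.DataFrame(
            {"ok": [0.0, 0.01, 0.5, 0.49], "sparse": [0.0, np.nan, 0.5, np.nan]},
            index=["c0", "c1", "t0", "t1"],
        )
        sel = select_differential(residuals, ["t0", "t1"], ["c0", "c1"], alpha=1.0)
        assert sel.n_skipped == 1
        assert sel.n_tested == 1

    def test_empty_group_error(self):
        residuals = pd.DataFrame({"a": [0.1, 0.2]}, index=["c0", "c1"])
        with pytest.raises(ValueError):
            select_differential(residuals, [], ["c0", "c1"])


class TestLineageScores:
    def _selection(self, pos, neg):
        from scmethdyn.statemodel import DifferentialSelection

        return DifferentialSelection(
            positive_sets=[(n, 1.0, 0.001) for n in pos],
            negative_sets=[(n, -1.0, 0.001) for n in neg],
            alpha=0.01,
            max_sets=20,
        )

    def test_mean_over_selected_sets(self):
        residuals = pd.DataFrame(
            {"p1": [0.1], "p2": [0.3], "n1": [-0.2]}, index=["s1"]
        )
        scores = lineage_scores(self._selection(["p1", "p2"], ["n1"]), residuals)
        assert scores.scores.loc["s1", "y_pos"] == pytest.approx(0.2)
        assert scores.scores.loc["s1", "x_neg"] == pytest.approx(-0.2)

    def test_direction_without_sets_missing(self):
        residuals = pd.DataFrame({"p1": [0.1]}, index=["s1"])
        scores = lineage_scores(self._selection(["p1"], []), residuals)
        assert np.isnan(scores.scores.loc["s1", "x_neg"])

    def test_sample_missing_all_negative_sets(self):
        residuals = pd.DataFrame({"p1": [0.1, 0.2], "n1": [np.nan, -0.1]}, index=["s1", "s2"])
        scores = lineage_scores(self._selection(["p1"], ["n1"]), residuals)
        assert np.isnan(scores.scores.loc["s1", "x_neg"])
        assert scores.scores.loc["s2", "x_neg"] == pytest.approx(-0.1)

    def test_empty_selection_error(self):
        with pytest.raises(ValueError):
            lineage_scores(self._selection([], []), pd.DataFrame({"a": [1.0]}))


class TestRunTrajectory:
    def test_controls_center_near_origin(self):
        matrix, cpg, truth, groups = simulate_regionset_matrix(seed=5)
        controls = [s for s in groups.index if groups[s] == "control"]
        treated = [s for s in groups.index if groups[s] == "treated"]
        res = run_trajectory(matrix, cpg, controls, treated)
        ctrl_means = res.scores.scores.loc[controls].mean()
        assert abs(ctrl_means["x_neg"]) < 0.02
        assert abs(ctrl_means["y_pos"]) < 0.02

    def test_recovers_truth_sets(self):
        matrix, cpg, truth, groups = simulate_regionset_matrix(seed=11)
        controls = [s for s in groups.index if groups[s] == "control"]
        treated = [s for s in groups.index if groups[s] == "treated"]
        res = run_trajectory(matrix, cpg, controls, treated)
        assert len(set(res.selection.positive_names) & set(truth.positive_sets)) >= 8
        assert len(set(res.selection.negative_names) & set(truth.negative_sets)) >= 8

    def test_swapped_groups_antisymmetric(self):
        matrix, cpg, truth, groups = simulate_regionset_matrix(
            seed=7,
            groups=(("control", 6, 0.0), ("treated", 6, 1.0)),
        )
        controls = [s for s in groups.index if groups[s] == "control"]
        treated = [s for s in groups.index if groups[s] == "treated"]
        fwd = run_trajectory(matrix, cpg, controls, treated)
        # swapping roles swaps the direction lists (same sets, opposite sign)
        rev_sel = select_differential(
            fwd.residual_table.residuals, treated_ids=controls, control_ids=treated
        )
        assert sorted(rev_sel.positive_names) == sorted(fwd.selection.negative_names)
        assert sorted(rev_sel.negative_names) == sorted(fwd.selection.positive_names)

    def test_single_endpoint_sample_selects_nothing(self):
        matrix, cpg, truth, groups = simulate_regionset_matrix(
            seed=3, groups=(("control", 4, 0.0), ("treated", 1, 1.0))
        )
        controls = [s for s in groups.index if groups[s] == "control"]
        treated = [s for s in groups.index if groups[s] == "treated"]
        with pytest.raises(ValueError, match="empty in both"):
            run_trajectory(matrix, cpg, controls, treated)

    def test_overlapping_groups_error(self):
        matrix, cpg, truth, groups = simulate_regionset_matrix(seed=3)
        ids = list(groups.index)
        with pytest.raises(ValueError, match="disjoint"):
            run_trajectory(matrix, cpg, ids[:4], ids[3:6])

    def test_methylation_score_mode_uses_raw_values(self):
        matrix, cpg, truth, groups = simulate_regionset_matrix(seed=19)
        controls = [s for s in groups.index if groups[s] == "control"]
        treated = [s for s in groups.index if groups[s] == "treated"]
        res = run_trajectory(matrix, cpg, controls, treated, score_mode="methylation")
        pos = res.selection.positive_names
        expected = matrix.values[pos].mean(axis=1)
        pd.testing.assert_series_equal(
            res.scores.scores["y_pos"], expected, check_names=False
        )
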