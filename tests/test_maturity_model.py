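"""Forest training, prediction, evaluation and importance diagnostics."""

import json

import numpy as np
import pandas as pd
import pytest

from ascmaturity.cohort import CohortTable
from ascmaturity.harmonize import MATURITY_MARKERS
from ascmaturity.maturity_model import (
    ForestModel,
    PredictionResult,
    TreeNodes,
    evaluate,
    hyperparameter_grid,
    minimal_depth_report,
    permutation_importance,
    predict,
    train_forest,
)
from .conftest import make_cohort


# ---------------------------------------------------------------------------
# independent oracles


def walk_tree_oracle(tree: TreeNodes, x: np.ndarray) -> float:
    """Recursive single-sample traversal, independent of TreeNodes.predict."""
    i = 0
    while tree.feature[i] >= 0:
        if x[tree.feature[i]] <= tree.threshold[i]:
            i = tree.left[i]
        else:
            i = tree.right[i]
    return float(tree.value[i])


def depth_oracle(fm: ForestModel):
    """Brute-force recursive traversal computing all depth-report fields."""
    p = len(fm.predictor_markers)
    roots = np.zeros(p)
    min_depth_sum = np.zeros(p)
    containing = np.zeros(p)
    nodes = np.zeros(p)

    def visit(tree, i, depth, seen):
        f = tree.feature[i]
        if f < 0:
            return
        nodes[f] += 1
        if f not in seen or depth < seen[f]:
            seen[f] = depth
        visit(tree, tree.left[i], depth + 1, seen)
        visit(tree, tree.right[i], depth + 1, seen)

    for tree in fm.trees:
        if tree.feature[0] >= 0:
            roots[tree.feature[0]] += 1
        seen: dict[int, int] = {}
        visit(tree, 0, 0, seen)
        for f, d in seen.items():
            containing[f] += 1
            min_depth_sum[f] += d
    return {
        "root_fraction": roots / len(fm.trees),
        "mean_minimal_depth": np.where(containing > 0,
                                       min_depth_sum / np.maximum(containing, 1),
                                       np.nan),
        "node_usage_fraction": nodes / nodes.sum(),
        "trees_containing": containing,
    }


def cart_split_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Enumerate all midpoints of adjacent sorted x; return the threshold
    maximizing variance reduction."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    best, best_thr = -np.inf, None
    for i in range(1, len(xs)):
        if xs[i] == xs[i - 1]:
            continue
        thr = (xs[i] + xs[i - 1]) / 2
        left, right = ys[:i], ys[i:]
        red = len(ys) * ys.var() - len(left) * left.var() - len(right) * right.var()
        if red > best:
            best, best_thr = red, thr
    return best_thr


def stacked_from(X: np.ndarray, y: np.ndarray, predictors) -> CohortTable:
    df = pd.DataFrame(X, columns=list(predictors))
    df["dpi"] = y
    df["sample_id"] = [f"s{i}" for i in range(len(y))]
    df["dataset_id"] = "d0"
    return CohortTable(df=df, markers=tuple(predictors))


# ---------------------------------------------------------------------------


class TestTrainForest:
    def test_constant_target(self, rng):
        X = rng.normal(size=(50, 8))
        table = stacked_from(X, np.full(50, 42.0), MATURITY_MARKERS)
        fm = train_forest(table, ntree=10, seed=0)
        np.testing.assert_allclose(fm.predict_matrix(X), 42.0)

    def test_first_split_matches_cart_oracle(self):
        # two distinct x values -> identical split under any bootstrap
        x = np.repeat([0.0, 1.0], 5)
        y = np.repeat([0.0, 10.0], 5)
        table = stacked_from(x[:, None], y, ["CD56"])
        fm = train_forest(table, predictors=("CD56",), ntree=1, mtry=1,
                          min_node_size=1, seed=0)
        assert fm.trees[0].threshold[0] == cart_split_oracle(x, y) == 0.5

    def test_step_function_oob_small(self, rng):
        # one predictor perfectly determines y up to noise via a step
        x = rng.choice([0.2, 0.8], 200)
        y = np.where(x < 0.5, 5.0, 100.0) + rng.normal(0, 1.0, 200)
        table = stacked_from(x[:, None], y, ["CD56"])
        fm = train_forest(table, predictors=("CD56",), ntree=50, mtry=1, seed=0)
        within_step_var = np.var(y[x < 0.5]) + np.var(y[x >= 0.5])
        assert fm.oob_mse < within_step_var

    def test_determinism_bit_identical(self, rng):
        X = rng.normal(size=(60, 8))
        y = rng.uniform(5, 180, 60)
        table = stacked_from(X, y, MATURITY_MARKERS)
        fm1 = train_forest(table, ntree=5, seed=3)
        fm2 = train_forest(table, ntree=5, seed=3)
        assert fm1.to_json() == fm2.to_json()

    def test_missing_predictor_errors(self, missing_cohort):
        with pytest.raises(ValueError, match="impute"):
            train_forest(missing_cohort, ntree=2)

    def test_mtry_exceeds_predictors_errors(self, small_cohort):
        with pytest.raises(ValueError, match="mtry"):
            train_forest(small_cohort, predictors=("CD56", "Ki67"), mtry=3)

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.uniform(5, 180, 40)
        fm = train_forest(stacked_from(X, y, MATURITY_MARKERS), ntree=3, seed=0)
        fm2 = ForestModel.from_json(fm.to_json())
        np.testing.assert_array_equal(fm.predict_matrix(X), fm2.predict_matrix(X))


class TestPredict:
    def leaf_forest(self, value=30.0, n_trees=4):
        tree = TreeNodes(
            feature=np.array([-1]), threshold=np.array([0.0]),
            left=np.array([-1]), right=np.array([-1]),
            value=np.array([value]), n_samples=np.array([10]),
        )
        return ForestModel(
            trees=[tree] * n_trees, predictor_markers=MATURITY_MARKERS,
            ntree=n_trees, mtry=6, min_node_size=5, seed=0,
            tree_seeds=np.zeros(n_trees, dtype=np.int64), n_training_rows=10,
            oob_mse=0.0, target_range=(value, value),
        )

    def test_identical_trees_give_their_value(self, small_cohort):
        res = predict(self.leaf_forest(30.0), small_cohort)
        assert (res.table["predicted_dpi"] == 30.0).all()

    def test_prediction_within_training_range(self, rng):
        X = rng.normal(size=(100, 8))
        y = rng.uniform(5, 180, 100)
        table = stacked_from(X, y, MATURITY_MARKERS)
        fm = train_forest(table, ntree=20, seed=0)
        preds = fm.predict_matrix(rng.normal(size=(50, 8)) * 10)
        assert preds.min() >= 5.0 and preds.max() <= 180.0

    def test_forest_equals_mean_of_tree_walk_oracle(self, rng):
        X = rng.normal(size=(60, 8))
        y = rng.uniform(5, 180, 60)
        fm = train_forest(stacked_from(X, y, MATURITY_MARKERS), ntree=7, seed=1)
        Xq = rng.normal(size=(20, 8))
        expected = np.array([
            np.mean([walk_tree_oracle(t, row) for t in fm.trees]) for row in Xq
        ])
        np.testing.assert_allclose(fm.predict_matrix(Xq), expected, rtol=0, atol=0)

    def test_memorized_row_recovered_at_purity(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.uniform(5, 180, 30)
        table = stacked_from(X, y, MATURITY_MARKERS)
        fm = train_forest(table, ntree=300, mtry=8, min_node_size=1, seed=0)
        pred0 = fm.predict_matrix(X[:1])[0]
        # bootstrap sampling error around the memorized target
        assert abs(pred0 - y[0]) < 25.0

    def test_incomplete_without_context_errors(self, missing_cohort):
        fm = self.leaf_forest()
        with pytest.raises(ValueError, match="context"):
            predict(fm, missing_cohort)

    def test_incomplete_with_context_averages_imputations(self, missing_cohort):
        fm = self.leaf_forest(30.0)
        complete = make_cohort(n=30, seed=9)
        res = predict(fm, missing_cohort, imputation_context=complete, m=3,
                      chain_iterations=1, seed=0)
        assert (res.table["predicted_dpi"] == 30.0).all()
        incomplete = missing_cohort.df[list(MATURITY_MARKERS)].isna().any(axis=1)
        assert (res.table.loc[incomplete.to_numpy(),
                              "n_imputations_averaged"] == 3).all()


class TestEvaluate:
    def pred_for(self, c, values):
        return PredictionResult(table=pd.DataFrame({
            "sample_id": c.df["sample_id"], "predicted_dpi": values,
            "n_imputations_averaged": 1}))

    def test_perfect_prediction(self, small_cohort):
        rep = evaluate(self.pred_for(small_cohort, small_cohort.df["dpi"]),
                       small_cohort)
        assert rep["r"] == pytest.approx(1.0)

    def test_anti_prediction(self, small_cohort):
        rep = evaluate(self.pred_for(small_cohort, -small_cohort.df["dpi"]),
                       small_cohort)
        assert rep["r"] == pytest.approx(-1.0)

    def test_pearson_matches_covariance_oracle(self, rng):
        c = make_cohort(n=10, seed=4)
        pred_vals = rng.uniform(5, 180, 10)
        rep = evaluate(self.pred_for(c, pred_vals), c)
        x = c.df["dpi"].to_numpy()
        y = pred_vals
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert rep["r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_too_few_overlaps_error(self):
        c = make_cohort(n=2, seed=0)
        with pytest.raises(ValueError):
            evaluate(self.pred_for(c, [1.0, 2.0]), c)

    def test_stage_table_and_trajectories_present(self, small_cohort):
        rep = evaluate(self.pred_for(small_cohort, small_cohort.df["dpi"]),
                       small_cohort)
        assert {"stage", "median_predicted_dpi", "ci_low", "ci_high"} <= \
            set(rep["per_stage"].columns)
        assert rep["trajectories"] is not None


class TestMinimalDepth:
    def test_single_tree_single_marker(self):
        k = list(MATURITY_MARKERS).index("CD56")
        tree = TreeNodes(
            feature=np.array([k, -1, -1]), threshold=np.array([0.5, 0, 0]),
            left=np.array([1, -1, -1]), right=np.array([2, -1, -1]),
            value=np.array([50.0, 20.0, 80.0]), n_samples=np.array([10, 5, 5]),
        )
        fm = ForestModel([tree], MATURITY_MARKERS, 1, 6, 5, 0,
                         np.zeros(1, dtype=np.int64), 10, 0.0, (5.0, 180.0))
        rep = minimal_depth_report(fm).table.set_index("marker")
        assert rep.loc["CD56", "root_fraction"] == 1.0
        assert rep.loc["CD56", "mean_minimal_depth"] == 0.0
        assert rep.loc["CD56", "node_usage_fraction"] == 1.0

    def test_five_tree_forest_matches_oracle_exactly(self, rng):
        X = rng.normal(size=(80, 8))
        y = rng.uniform(5, 180, 80)
        fm = train_forest(stacked_from(X, y, MATURITY_MARKERS), ntree=5,
                          mtry=3, seed=2)
        rep = minimal_depth_report(fm).table
        oracle = depth_oracle(fm)
        np.testing.assert_array_equal(rep["root_fraction"], oracle["root_fraction"])
        np.testing.assert_array_equal(rep["node_usage_fraction"],
                                      oracle["node_usage_fraction"])
        np.testing.assert_array_equal(rep["trees_containing"],
                                      oracle["trees_containing"])
        np.testing.assert_allclose(rep["mean_minimal_depth"],
                                   oracle["mean_minimal_depth"])

    def test_fractions_sum_to_one(self, rng):
        X = rng.normal(size=(100, 8))
        y = rng.uniform(5, 180, 100)
        fm = train_forest(stacked_from(X, y, MATURITY_MARKERS), ntree=20, seed=0)
        rep = minimal_depth_report(fm).table
        assert rep["root_fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        assert rep["node_usage_fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_unused_marker_reported_absent(self, rng):
        # train on one informative predictor only; others never used
        x = rng.uniform(0, 1, 60)
        X = np.column_stack([x, np.zeros(60)])
        fm = train_forest(stacked_from(X, 100 * x, ["CD56", "CD20"]),
                          predictors=("CD56", "CD20"), ntree=5, mtry=1, seed=0)
        rep = minimal_depth_report(fm).table.set_index("marker")
        # CD20 is constant: if ever drawn it cannot split
        assert rep.loc["CD20", "trees_containing"] == 0
        assert np.isnan(rep.loc["CD20", "mean_minimal_depth"])


class TestPermutationImportance:
    def informative_table(self, rng, n=200):
        X = rng.normal(size=(n, 8))
        y = 50 + 40 * X[:, list(MATURITY_MARKERS).index("CD56")]
        return stacked_from(X, y, MATURITY_MARKERS)

    def test_sole_informative_marker_ranks_first(self, rng):
        table = self.informative_table(rng)
        fm = train_forest(table, ntree=30, mtry=3, seed=0)
        rep = permutation_importance(fm, table, seed=0).table.set_index("marker")
        assert rep["mse_increase"].idxmax() == "CD56"

    def test_noise_marker_near_zero(self, rng):
        table = self.informative_table(rng)
        fm = train_forest(table, ntree=30, mtry=3, seed=0)
        rep = permutation_importance(fm, table, seed=0).table.set_index("marker")
        noise = rep.drop("CD56")["mse_increase"]
        assert noise.abs().max() < rep.loc["CD56", "mse_increase"] / 5

    def test_single_oob_row_gives_zero_increase(self):
        tree = TreeNodes(np.array([-1]), np.array([0.0]), np.array([-1]),
                         np.array([-1]), np.array([42.0]), np.array([1]))
        fm = ForestModel([tree], ("CD56",), 1, 1, 5, 0,
                         np.zeros(1, dtype=np.int64), 5, 0.0, (42.0, 42.0))
        df = pd.DataFrame({"CD56": [1.0], "dpi": [42.0], "sample_id": ["s0"],
                           "dataset_id": ["d0"]})
        data = CohortTable(df=df, markers=("CD56",))
        rep = permutation_importance(fm, data, seed=0).table
        assert (rep["mse_increase"] == 0.0).all()


class TestHyperparameterGrid:
    def test_single_combination(self, rng):
        table = make_cohort(n=60, seed=0)
        val = make_cohort(n=30, seed=1)
        res = hyperparameter_grid(table, val, ntree_grid=(10,), mtry_grid=(3,))
        assert len(res) == 1
        assert {"train_r", "validation_r"} <= set(res.columns)

    def test_full_default_grid_shape(self, rng):
        table = make_cohort(n=40, seed=0)
        val = make_cohort(n=20, seed=1)
        res = hyperparameter_grid(table, val, ntree_grid=(5, 10),
                                  mtry_grid=(3, 4, 5, 6, 7))
        assert len(res) == 10
        assert res["validation_r"].is_monotonic_decreasing

    def test_no_ki67_subset(self):
        table = make_cohort(n=40, seed=0)
        val = make_cohort(n=20, seed=1)
        subset = tuple(m for m in MATURITY_MARKERS if m != "Ki67")
        res = hyperparameter_grid(table, val, ntree_grid=(5,), mtry_grid=(7, 8),
                                  predictor_subsets=[subset])
        # mtry=8 > 7 predictors is skipped
        assert len(res) == 1
        assert res.iloc[0]["n_predictors"] == 7
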