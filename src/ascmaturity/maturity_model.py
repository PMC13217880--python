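"""The maturity model: a random-forest regressor of day post-immune-intervention
(DPI) on eight normalized ASC markers, with introspectable trees.

The model predicts the DPI of a blood sample from the normalized expression
of CD19, CD20, CD28, CD45, CD56, CD138, HLA-DR and Ki67 by its ASCs; the
predicted DPI serves as a surrogate for average ASC maturity, so the model
can be applied to samples of unknown immune state (tissues, disease cohorts).

Each tree is grown CART-style on a bootstrap resample with ``mtry`` candidate
predictors per split and immediately extracted into a flat node-list
(split marker, threshold, children, leaf value, node size), which makes the
importance diagnostics — minimal tree depth, root fraction, node-usage share
and out-of-bag (OOB) permutation MSE increase — exact tree-walks rather than
library-dependent approximations. Bootstrap membership per tree is derived
from a stored per-tree seed, so OOB rows are reproducible from the serialized
model alone. Defaults: ntree=100, mtry=6, minimum terminal-node size 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .cohort import CohortTable, assign_stage_column
from .harmonize import MATURITY_MARKERS
from . import stats as _stats

__all__ = [
    "TreeNodes",
    "ForestModel",
    "PredictionResult",
    "ImportanceReport",
    "train_forest",
    "predict",
    "evaluate",
    "minimal_depth_report",
    "permutation_importance",
    "hyperparameter_grid",
]


@dataclass
class TreeNodes:
    """One regression tree as parallel node arrays (index 0 = root).

    A negative ``feature[i]`` marks a leaf; internal nodes send rows with
    ``x[feature] <= threshold`` left.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_samples: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feat = self.feature[idx]
            active = np.flatnonzero(feat >= 0)
            if active.size == 0:
                break
            cur = idx[active]
            go_left = X[active, feat[active]] <= self.threshold[cur]
            idx[active] = np.where(go_left, self.left[cur], self.right[cur])
        return self.value[idx]

    def node_depths(self) -> np.ndarray:
        depths = np.zeros(len(self.feature), dtype=np.int64)
        order = [0]
        while order:
            i = order.pop()
            if self.feature[i] >= 0:
                for child in (self.left[i], self.right[i]):
                    depths[child] = depths[i] + 1
                    order.append(child)
        return depths


def _extract_tree(sk_tree: DecisionTreeRegressor) -> TreeNodes:
    t = sk_tree.tree_
    return TreeNodes(
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        left=t.children_left.copy(),
        right=t.children_right.copy(),
        value=t.value.reshape(-1).copy(),
        n_samples=t.n_node_samples.copy(),
    )


@dataclass
class ForestModel:
    """Regression forest with fully introspectable trees."""

    trees: list[TreeNodes]
    predictor_markers: tuple[str, ...]
    ntree: int
    mtry: int
    min_node_size: int
    seed: int
    tree_seeds: np.ndarray
    n_training_rows: int
    oob_mse: float
    target_range: tuple[float, float]

    def bootstrap_indices(self, tree_idx: int) -> np.ndarray:
        rng = np.random.default_rng(int(self.tree_seeds[tree_idx]))
        return rng.integers(0, self.n_training_rows, self.n_training_rows)

    def oob_indices(self, tree_idx: int) -> np.ndarray:
        inbag = np.zeros(self.n_training_rows, dtype=bool)
        inbag[self.bootstrap_indices(tree_idx)] = True
        return np.flatnonzero(~inbag)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees of the per-tree leaf values."""
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / len(self.trees)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "predictor_markers": list(self.predictor_markers),
            "ntree": self.ntree,
            "mtry": self.mtry,
            "min_node_size": self.min_node_size,
            "seed": self.seed,
            "tree_seeds": [int(s) for s in self.tree_seeds],
            "n_training_rows": self.n_training_rows,
            "oob_mse": self.oob_mse,
            "target_range": list(self.target_range),
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                    "n_samples": t.n_samples.tolist(),
                }
                for t in self.trees
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        d = json.loads(text)
        trees = [
            TreeNodes(
                feature=np.array(t["feature"], dtype=np.int64),
                threshold=np.array(t["threshold"], dtype=float),
                left=np.array(t["left"], dtype=np.int64),
                right=np.array(t["right"], dtype=np.int64),
                value=np.array(t["value"], dtype=float),
                n_samples=np.array(t["n_samples"], dtype=np.int64),
            )
            for t in d["trees"]
        ]
        return cls(
            trees=trees,
            predictor_markers=tuple(d["predictor_markers"]),
            ntree=d["ntree"],
            mtry=d["mtry"],
            min_node_size=d["min_node_size"],
            seed=d["seed"],
            tree_seeds=np.array(d["tree_seeds"], dtype=np.int64),
            n_training_rows=d["n_training_rows"],
            oob_mse=d["oob_mse"],
            target_range=tuple(d["target_range"]),
        )


def train_forest(
    stacked: CohortTable,
    predictors=MATURITY_MARKERS,
    target: str = "dpi",
    ntree: int = 100,
    mtry: int = 6,
    min_node_size: int = 5,
    seed: int = 0,
) -> ForestModel:
    """Fit the regression forest on a complete (imputed, stacked) table.

    Per tree: bootstrap rows with replacement, CART variance-reduction
    splitting over ``mtry`` uniformly sampled candidate predictors per node,
    stop when a node would leave fewer than ``min_node_size`` rows in a leaf
    or has zero target variance; leaf value = mean target. OOB MSE is
    recorded over rows with at least one OOB tree.
    """
    predictors = tuple(predictors)
    if mtry > len(predictors):
        raise ValueError(f"mtry={mtry} exceeds the {len(predictors)} predictors")
    X_df = stacked.df[list(predictors)]
    if X_df.isna().any().any():
        raise ValueError("predictors contain missing values; impute before training")
    y = stacked.df[target].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"target {target!r} contains missing values")
    X = X_df.to_numpy(dtype=float)
    n = len(y)

    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=ntree)

    trees: list[TreeNodes] = []
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=np.int64)
    model = ForestModel(
        trees=trees, predictor_markers=predictors, ntree=ntree, mtry=mtry,
        min_node_size=min_node_size, seed=seed, tree_seeds=tree_seeds,
        n_training_rows=n, oob_mse=float("nan"),
        target_range=(float(y.min()), float(y.max())),
    )
    for t_idx, t_seed in enumerate(tree_seeds):
        boot = model.bootstrap_indices(t_idx)
        sk = DecisionTreeRegressor(
            criterion="squared_error",
            max_features=mtry,
            min_samples_leaf=min_node_size,
            random_state=int(t_seed),
        )
        sk.fit(X[boot], y[boot])
        tree = _extract_tree(sk)
        trees.append(tree)
        oob = model.oob_indices(t_idx)
        if oob.size:
            oob_sum[oob] += tree.predict(X[oob])
            oob_cnt[oob] += 1
    covered = oob_cnt > 0
    if covered.any():
        resid = y[covered] - oob_sum[covered] / oob_cnt[covered]
        model.oob_mse = float(np.mean(resid**2))
    return model


@dataclass
class PredictionResult:
    """Per-sample predicted DPI (days), averaged over trees and imputations."""

    table: pd.DataFrame  # sample_id, predicted_dpi, n_imputations_averaged

    def series(self) -> pd.Series:
        return self.table.set_index("sample_id")["predicted_dpi"]


def predict(
    fm: ForestModel,
    samples: CohortTable,
    imputation_context: CohortTable | None = None,
    m: int = 20,
    chain_iterations: int = 5,
    seed: int = 0,
) -> PredictionResult:
    """Predict DPI for new samples.

    Complete samples are pushed through the forest directly. Samples with
    missing predictors are imputed *m* times jointly with the supplied
    context cohort (typically the training cohort), predicted per completed
    copy, and averaged.
    """
    preds = list(fm.predictor_markers)
    df = samples.df
    obs_counts = df[preds].notna().sum(axis=1)
    if (obs_counts == 0).any():
        raise ValueError("samples with no observed predictor cannot be scored")
    incomplete = df[preds].isna().any(axis=1)
    out = pd.DataFrame({
        "sample_id": df["sample_id"].to_numpy(),
        "predicted_dpi": np.nan,
        "n_imputations_averaged": 1,
    })
    if (~incomplete).any():
        X = df.loc[~incomplete, preds].to_numpy(dtype=float)
        out.loc[(~incomplete).to_numpy(), "predicted_dpi"] = fm.predict_matrix(X)
    if incomplete.any():
        if imputation_context is None:
            raise ValueError(
                "samples have missing predictors; supply an imputation context"
            )
        from .impute import mice_rf

        ctx = imputation_context.df
        combined = pd.concat(
            [ctx, df[incomplete.to_numpy()]], ignore_index=True
        )
        combined = combined.assign(
            sample_id=[f"r{i}" for i in range(len(combined))]
        )
        joint = CohortTable(df=combined, markers=tuple(preds))
        bundle = mice_rf(joint, markers=preds, m=m,
                         chain_iterations=chain_iterations, seed=seed)
        tail = slice(len(ctx), len(combined))
        acc = np.zeros(int(incomplete.sum()))
        for table in bundle.tables:
            X = table.df.iloc[tail][preds].to_numpy(dtype=float)
            acc += fm.predict_matrix(X)
        out.loc[incomplete.to_numpy(), "predicted_dpi"] = acc / bundle.m
        out.loc[incomplete.to_numpy(), "n_imputations_averaged"] = bundle.m
    return PredictionResult(table=out)


def evaluate(pred: PredictionResult, truth: CohortTable) -> dict:
    """Correlate predicted with actual DPI and summarize by stage and subject.

    Returns a dict with the Pearson ``r`` (and p), its qualitative label,
    a per-stage table (median predicted DPI with a 1.57*IQR/sqrt(n) notch-style
    95% CI), and per-subject longitudinal trajectories ordered by actual DPI.
    """
    merged = pred.table.merge(
        truth.df[[c for c in ("sample_id", "dpi", "subject_id", "dataset_id")
                  if c in truth.df.columns]],
        on="sample_id",
    ).dropna(subset=["dpi", "predicted_dpi"])
    if len(merged) < 3:
        raise ValueError("need at least 3 overlapping samples to evaluate")
    r, p = _stats.pearson(merged["dpi"].to_numpy(), merged["predicted_dpi"].to_numpy())

    merged["stage"] = assign_stage_column(merged)
    stage_rows = []
    for stage, grp in merged.groupby("stage"):
        vals = grp["predicted_dpi"].to_numpy()
        med = float(np.median(vals))
        iqr = float(np.subtract(*np.percentile(vals, [75, 25])))
        half = 1.57 * iqr / np.sqrt(len(vals))
        stage_rows.append({"stage": stage, "n": len(vals), "median_predicted_dpi": med,
                           "ci_low": med - half, "ci_high": med + half})
    per_stage = pd.DataFrame(stage_rows)

    trajectories = None
    if "subject_id" in merged.columns:
        trajectories = (merged.sort_values(["subject_id", "dpi"])
                        [["subject_id", "dpi", "predicted_dpi"]]
                        .reset_index(drop=True))
    return {
        "r": r,
        "p": p,
        "n": len(merged),
        "label": _stats.classify_correlation(r),
        "per_stage": per_stage,
        "trajectories": trajectories,
    }


@dataclass
class ImportanceReport:
    """Per-predictor importance diagnostics (one row per marker)."""

    table: pd.DataFrame


def minimal_depth_report(fm: ForestModel) -> ImportanceReport:
    """Structural importance by exact tree traversal.

    Per marker: fraction of trees whose root splits on it, mean minimal depth
    over the trees that use it (root = depth 0), its share of all internal
    nodes, and the number of trees containing it.
    """
    p = len(fm.predictor_markers)
    root_counts = np.zeros(p)
    min_depth_sums = np.zeros(p)
    trees_containing = np.zeros(p, dtype=int)
    node_counts = np.zeros(p)
    for tree in fm.trees:
        depths = tree.node_depths()
        internal = tree.feature >= 0
        if internal[0]:
            root_counts[tree.feature[0]] += 1
        for k in range(p):
            mask = internal & (tree.feature == k)
            node_counts[k] += mask.sum()
            if mask.any():
                trees_containing[k] += 1
                min_depth_sums[k] += depths[mask].min()
    total_internal = node_counts.sum()
    with np.errstate(invalid="ignore"):
        mean_min_depth = np.where(trees_containing > 0,
                                  min_depth_sums / np.maximum(trees_containing, 1),
                                  np.nan)
    table = pd.DataFrame({
        "marker": list(fm.predictor_markers),
        "root_fraction": root_counts / len(fm.trees),
        "mean_minimal_depth": mean_min_depth,
        "node_usage_fraction": node_counts / total_internal if total_internal else 0.0,
        "trees_containing": trees_containing,
    })
    return ImportanceReport(table=table)


def permutation_importance(
    fm: ForestModel,
    data: CohortTable,
    target: str = "dpi",
    seed: int = 0,
) -> ImportanceReport:
    """OOB permutation importance: raw MSE increase in days^2.

    When *data* is the training table (row count matches), each tree is
    scored on its own OOB rows; otherwise all rows act as held-out for every
    tree. Per tree and marker, the marker's column is permuted among the
    scored rows and the MSE increase (permuted - original) recorded;
    ``mse_increase`` is the mean over trees.
    """
    preds = list(fm.predictor_markers)
    X = data.df[preds].to_numpy(dtype=float)
    y = data.df[target].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("permutation importance needs complete data with target")
    use_oob = len(y) == fm.n_training_rows
    rng = np.random.default_rng(seed)
    p = len(preds)
    increases = np.zeros(p)
    used = np.zeros(p)
    for t_idx, tree in enumerate(fm.trees):
        rows = fm.oob_indices(t_idx) if use_oob else np.arange(len(y))
        if rows.size == 0:
            continue
        Xr = X[rows]
        yr = y[rows]
        base_mse = float(np.mean((tree.predict(Xr) - yr) ** 2))
        for k in range(p):
            perm = rng.permutation(rows.size)
            if rows.size == 1:
                increases[k] += 0.0
                used[k] += 1
                continue
            Xp = Xr.copy()
            Xp[:, k] = Xr[perm, k]
            mse = float(np.mean((tree.predict(Xp) - yr) ** 2))
            increases[k] += mse - base_mse
            used[k] += 1
    table = pd.DataFrame({
        "marker": preds,
        "mse_increase": increases / np.maximum(used, 1),
    })
    return ImportanceReport(table=table)


def hyperparameter_grid(
    stacked: CohortTable,
    validation: CohortTable,
    ntree_grid=(100, 200, 300, 500),
    mtry_grid=(3, 4, 5, 6, 7),
    predictor_subsets=None,
    target: str = "dpi",
    seed: int = 0,
) -> pd.DataFrame:
    """Train/evaluate every (ntree, mtry, predictor-subset) combination.

    *validation* must be complete on the predictors. Rows are sorted by
    validation r (descending). mtry values exceeding a subset's size are
    skipped for that subset. The no-Ki67 alternative model is one subset run.
    """
    if predictor_subsets is None:
        predictor_subsets = [tuple(MATURITY_MARKERS)]
    rows = []
    for subset in predictor_subsets:
        subset = tuple(subset)
        for ntree in ntree_grid:
            for mtry in mtry_grid:
                if mtry > len(subset):
                    continue
                fm = train_forest(stacked, predictors=subset, target=target,
                                  ntree=ntree, mtry=mtry, seed=seed)
                pred_tr = PredictionResult(table=pd.DataFrame({
                    "sample_id": stacked.df["sample_id"],
                    "predicted_dpi": fm.predict_matrix(
                        stacked.df[list(subset)].to_numpy(dtype=float)),
                    "n_imputations_averaged": 1,
                }))
                # stacked tables repeat sample ids; correlate directly
                r_train, _ = _stats.pearson(
                    stacked.df[target].to_numpy(dtype=float),
                    pred_tr.table["predicted_dpi"].to_numpy(),
                )
                Xv = validation.df[list(subset)].to_numpy(dtype=float)
                r_val, _ = _stats.pearson(
                    validation.df[target].to_numpy(dtype=float),
                    fm.predict_matrix(Xv),
                )
                rows.append({
                    "predictors": ",".join(subset),
                    "n_predictors": len(subset),
                    "ntree": ntree,
                    "mtry": mtry,
                    "train_r": r_train,
                    "validation_r": r_val,
                    "oob_mse": fm.oob_mse,
                })
    return (pd.DataFrame(rows)
            .sort_values("validation_r", ascending=False)
            .reset_index(drop=True))
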