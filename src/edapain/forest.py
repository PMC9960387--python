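"""Two-output regression forest, impurity importance and recursive feature
elimination.

The binary task is pair-encoded: each window's label becomes a regression
target (1, 0) for the negative class and (0, 1) for the positive class, and a
random forest regressor with two outputs is fit with mean-squared-error
impurity (100 trees, min_samples_split 2, unlimited depth). A window is
classified by averaging the per-tree outputs and taking the larger slot, with
exact ties resolved to the negative (no-pain) class.

Feature importance is the classical mean-decrease-in-impurity: at every
internal node j,

    n_j = w_j C_j - w_left C_left - w_right C_right,

where C is the node's MSE impurity and w the weighted fraction of training
samples reaching it; a feature's score is the sum of n_j over the nodes that
split on it, normalised so scores sum to 1, then averaged over trees. Fitting
and prediction are delegated to scikit-learn; the importance is computed here
by traversing the fitted trees directly, which also serves as an executable
statement of the formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .evaluation import loso_folds_from_arrays

__all__ = [
    "ForestConfig",
    "FittedForest",
    "encode_targets",
    "fit_forest",
    "predict_label",
    "impurity_importance",
    "tree_impurity_importance",
    "run_rfe",
    "RFEResult",
]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 100
    min_samples_split: int = 2
    max_depth: int | None = None
    bootstrap: bool = True
    seed: int = 0


@dataclass
class FittedForest:
    model: RandomForestRegressor
    feature_names: tuple[str, ...]
    classes: tuple[str, str]  # (negative, positive); slot order of the outputs

    @property
    def trees(self):
        return self.model.estimators_


def encode_targets(labels: np.ndarray, negative: str, positive: str) -> np.ndarray:
    """Pair-encode labels as (1,0)/(0,1) two-output regression targets."""
    labels = np.asarray(labels)
    unknown = set(labels) - {negative, positive}
    if unknown:
        raise ValueError(f"labels outside the task: {sorted(unknown)}")
    y = np.zeros((labels.size, 2))
    y[labels == negative, 0] = 1.0
    y[labels == positive, 1] = 1.0
    return y


def fit_forest(features: pd.DataFrame, labels: np.ndarray,
               negative: str, positive: str,
               cfg: ForestConfig = ForestConfig()) -> FittedForest:
    """Fit the two-output forest on a feature frame (feature columns only)."""
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both labels")
    y = encode_targets(labels, negative, positive)
    model = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        min_samples_split=cfg.min_samples_split,
        max_depth=cfg.max_depth,
        bootstrap=cfg.bootstrap,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return FittedForest(model=model, feature_names=tuple(features.columns),
                        classes=(negative, positive))


def predict_label(forest: FittedForest, features: pd.DataFrame) -> np.ndarray:
    """Average the two regression outputs over trees and take the larger slot.

    An exact tie goes to the negative (no-pain) slot.
    """
    missing = [c for c in forest.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = features[list(forest.feature_names)].to_numpy(dtype=float)
    pred = forest.model.predict(X)
    pick = pred[:, 1] > pred[:, 0]  # ties -> negative class
    return np.where(pick, forest.classes[1], forest.classes[0])


def tree_impurity_importance(tree, n_features: int) -> np.ndarray:
    """Mean-decrease-in-impurity scores for one fitted decision tree.

    Traverses the tree structure directly: per internal node the impurity
    decrease n_j is accumulated on the split feature, then the vector is
    normalised to sum to 1 (all-leaf trees return zeros).
    """
    t = tree.tree_
    total_w = t.weighted_n_node_samples[0]
    scores = np.zeros(n_features)
    for j in range(t.node_count):
        left, right = t.children_left[j], t.children_right[j]
        if left == -1:  # leaf
            continue
        w_j = t.weighted_n_node_samples[j] / total_w
        w_l = t.weighted_n_node_samples[left] / total_w
        w_r = t.weighted_n_node_samples[right] / total_w
        n_j = w_j * t.impurity[j] - w_l * t.impurity[left] - w_r * t.impurity[right]
        scores[t.feature[j]] += n_j
    total = scores.sum()
    if total > 0:
        scores /= total
    return scores


def impurity_importance(forest: FittedForest) -> pd.Series:
    """Per-feature importance averaged over trees; sums to 1 if any tree split."""
    n = len(forest.feature_names)
    acc = np.zeros(n)
    for tree in forest.trees:
        acc += tree_impurity_importance(tree, n)
    acc /= len(forest.trees)
    total = acc.sum()
    if total > 0:
        acc /= total
    return pd.Series(acc, index=list(forest.feature_names), name="importance")


@dataclass
class RFEResult:
    """Recursive-feature-elimination trace.

    ``iterations`` holds, per step, the retained feature names and the LOSO
    accuracy achieved with them; feature sets are nested and shrink by one.
    """

    iterations: list[tuple[tuple[str, ...], float]]

    @property
    def best_index(self) -> int:
        return int(np.argmax([acc for _, acc in self.iterations]))

    @property
    def best_accuracy(self) -> float:
        return self.iterations[self.best_index][1]

    @property
    def best_features(self) -> tuple[str, ...]:
        return self.iterations[self.best_index][0]

    @property
    def full_feature_accuracy(self) -> float:
        return self.iterations[0][1]

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(len(f), acc) for f, acc in self.iterations],
            columns=["n_features", "accuracy"],
        )


def _loso_forest_pass(X: pd.DataFrame, labels: np.ndarray, groups: np.ndarray,
                      negative: str, positive: str, cfg: ForestConfig
                      ) -> tuple[float, np.ndarray]:
    """One LOSO sweep: per-fold fit, pooled accuracy and fold-averaged
    importances over the current feature set."""
    folds = loso_folds_from_arrays(groups)
    n_correct = 0
    importance = np.zeros(X.shape[1])
    for test_subject, train_mask, test_mask in folds:
        f = fit_forest(X[train_mask], labels[train_mask], negative, positive,
                       cfg)
        pred = predict_label(f, X[test_mask])
        n_correct += int((pred == labels[test_mask]).sum())
        importance += impurity_importance(f).to_numpy()
    importance /= len(folds)
    return n_correct / X.shape[0], importance


def run_rfe(features: pd.DataFrame, labels: np.ndarray, groups: np.ndarray,
            negative: str, positive: str,
            cfg: ForestConfig = ForestConfig(),
            min_features: int = 1) -> RFEResult:
    """Recursive feature elimination under leave-one-subject-out evaluation.

    Per iteration the forest is fit on every LOSO fold; importances are
    averaged across folds, the least important feature is dropped (ties break
    towards the earlier registry column) and the pooled LOSO accuracy is
    recorded. Stops at ``min_features``.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least two features")
    groups = np.asarray(groups)
    if len(set(groups)) < 2:
        raise ValueError("need at least two subjects for LOSO")
    labels = np.asarray(labels)
    current = list(features.columns)
    iterations: list[tuple[tuple[str, ...], float]] = []
    while True:
        acc, importance = _loso_forest_pass(
            features[current], labels, groups, negative, positive, cfg)
        iterations.append((tuple(current), acc))
        if len(current) <= min_features:
            break
        drop = int(np.argmin(importance))  # first occurrence wins ties
        current = current[:drop] + current[drop + 1:]
    return RFEResult(iterations=iterations)
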