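"""Two-output regression forest, impurity importance and RFE."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from edapain.forest import (FittedForest, ForestConfig, encode_targets,
                            fit_forest, impurity_importance, predict_label,
                            run_rfe, tree_impurity_importance)

NEG, POS = "no_pain", "high_pain"


def _separable(n=60, n_noise=3, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([NEG, POS] * (n // 2))
    signal = np.where(labels == POS, 1.0, 0.0) + rng.normal(0, 0.05, n)
    cols = {"signal": signal}
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.normal(size=n)
    return pd.DataFrame(cols), labels


class TestEncodeAndFit:
    def test_pair_encoding(self):
        y = encode_targets(np.array([NEG, POS, NEG]), NEG, POS)
        assert y.tolist() == [[1, 0], [0, 1], [1, 0]]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            encode_targets(np.array([NEG, "weird"]), NEG, POS)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_forest(X, np.array([NEG, NEG]), NEG, POS)

    def test_separable_training_accuracy(self):
        X, labels = _separable()
        f = fit_forest(X, labels, NEG, POS, ForestConfig(seed=0))
        assert (predict_label(f, X) == labels).mean() == 1.0

    def test_fixed_seed_is_deterministic(self):
        X, labels = _separable()
        a = fit_forest(X, labels, NEG, POS, ForestConfig(seed=7))
        b = fit_forest(X, labels, NEG, POS, ForestConfig(seed=7))
        assert np.array_equal(a.model.predict(X.to_numpy()),
                              b.model.predict(X.to_numpy()))

    def test_row_duplication_leaves_held_out_predictions_stable(self):
        X, labels = _separable(n=80)
        X_test, y_test = _separable(n=40, seed=99)
        accs, accs_dup = [], []
        X_dup = pd.concat([X, X], ignore_index=True)
        labels_dup = np.concatenate([labels, labels])
        for seed in range(10):
            cfg = ForestConfig(n_trees=50, seed=seed)
            f = fit_forest(X, labels, NEG, POS, cfg)
            accs.append((predict_label(f, X_test) == y_test).mean())
            f2 = fit_forest(X_dup, labels_dup, NEG, POS, cfg)
            accs_dup.append((predict_label(f2, X_test) == y_test).mean())
        assert abs(np.mean(accs) - np.mean(accs_dup)) <= 0.02


class TestPredictLabel:
    class _Stub:
        def __init__(self, out):
            self._out = np.asarray(out)

        def predict(self, X):
            return self._out[: len(X)]

    def test_argmax_and_tie_break(self):
        ff = FittedForest(model=self._Stub([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]]),
                          feature_names=("a",), classes=(NEG, POS))
        X = pd.DataFrame({"a": [0.0, 0.0, 0.0]})
        assert predict_label(ff, X).tolist() == [NEG, NEG, POS]

    def test_missing_column_rejected(self):
        ff = FittedForest(model=self._Stub([[1, 0]]), feature_names=("a", "b"),
                          classes=(NEG, POS))
        with pytest.raises(ValueError, match="missing feature"):
            predict_label(ff, pd.DataFrame({"a": [1.0]}))


class TestImpurityImportance:
    def test_depth_one_tree_oracle(self):
        # 4 samples, feature A splits targets (0,0,1,1) perfectly:
        # root MSE impurity 0.25, children pure, all credit on A
        X = np.array([[0.0, 5.0], [0.0, 5.0], [1.0, 5.0], [1.0, 5.0]])
        y = encode_targets(np.array([NEG, NEG, POS, POS]), NEG, POS)
        tree = DecisionTreeRegressor(random_state=0).fit(X, y)
        assert tree.tree_.impurity[0] == pytest.approx(0.25)
        scores = tree_impurity_importance(tree, 2)
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == 0.0

    def test_matches_sklearn_importances(self):
        # independent route: sklearn's own mean-decrease-in-impurity
        X, labels = _separable(n=100, n_noise=5, seed=2)
        f = fit_forest(X, labels, NEG, POS, ForestConfig(seed=1))
        mine = impurity_importance(f).to_numpy()
        theirs = f.model.feature_importances_
        assert np.allclose(mine, theirs, atol=1e-10)

    def test_nonnegative_and_sums_to_one(self, small_windowset):
        from edapain.features import extract_features
        df = extract_features(small_windowset)
        cols = [c for c in df.columns if c not in ("subject_id", "label")]
        f = fit_forest(df[cols], df["label"].to_numpy(), NEG, POS,
                       ForestConfig(n_trees=20, seed=0))
        imp = impurity_importance(f)
        assert (imp >= 0).all()
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unused_feature_has_zero_importance(self):
        X, labels = _separable()
        X["constant"] = 1.0  # never splittable
        f = fit_forest(X, labels, NEG, POS, ForestConfig(seed=0))
        assert impurity_importance(f)["constant"] == 0.0

    def test_column_permutation_equivariance(self):
        X, labels = _separable(n=100, n_noise=4, seed=3)
        f = fit_forest(X, labels, NEG, POS, ForestConfig(seed=5))
        imp = impurity_importance(f)
        perm = list(reversed(X.columns))
        f2 = fit_forest(X[perm], labels, NEG, POS, ForestConfig(seed=5))
        imp2 = impurity_importance(f2)
        assert np.allclose(imp.reindex(perm).to_numpy(), imp2.to_numpy(),
                           atol=1e-9)

    def test_duplicated_column_importance_splits_but_sums(self):
        X, labels = _separable(n=80, n_noise=2, seed=4)
        base = np.mean([impurity_importance(
            fit_forest(X, labels, NEG, POS, ForestConfig(n_trees=50, seed=s))
        )["signal"] for s in range(10)])
        X2 = X.copy()
        X2["signal_copy"] = X2["signal"]
        dup = np.mean([
            impurity_importance(
                fit_forest(X2, labels, NEG, POS,
                           ForestConfig(n_trees=50, seed=s))
            )[["signal", "signal_copy"]].sum() for s in range(10)
        ])
        assert abs(base - dup) <= 0.05


class TestRFE:
    def test_recovers_informative_features(self):
        rng = np.random.default_rng(0)
        n = 96
        labels = np.array([NEG, POS] * (n // 2))
        groups = np.repeat([f"S{i}" for i in range(8)], n // 8)
        data = {"inf_a": (labels == POS) + rng.normal(0, 0.05, n),
                "inf_b": (labels == POS) + rng.normal(0, 0.05, n)}
        for j in range(20):
            data[f"noise_{j}"] = rng.normal(size=n)
        X = pd.DataFrame(data)
        res = run_rfe(X, labels, groups, NEG, POS,
                      ForestConfig(n_trees=20, seed=0))
        assert len(res.iterations) == X.shape[1]
        # strictly shrinking, nested feature sets
        sizes = [len(f) for f, _ in res.iterations]
        assert sizes == list(range(X.shape[1], 0, -1))
        for (a, _), (b, _) in zip(res.iterations, res.iterations[1:]):
            assert set(b) <= set(a)
        assert set(res.iterations[-2][0]) == {"inf_a", "inf_b"}

    def test_requires_two_subjects_and_two_features(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            run_rfe(X, np.array([NEG, POS]), np.array(["S0", "S0"]), NEG, POS)
        with pytest.raises(ValueError):
            run_rfe(X[["a"]], np.array([NEG, POS]),
                    np.array(["S0", "S1"]), NEG, POS)
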