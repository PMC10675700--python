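"""CART trees and the bagged forest: split optimality, determinism,
ensemble behaviour, and agreement with an independent implementation."""

import numpy as np
import pytest

from sowtherm.errors import ConfigurationError, ShapeMismatchError
from sowtherm.forest import (ForestHyperparams, ForestModel, fit_forest,
                             fit_tree, predict)


def exhaustive_best_split(X, y, min_samples_leaf=1):
    """Brute-force best (feature, threshold) by SSE reduction with the
    documented tie-break: lowest feature index, then lowest threshold."""
    n, p = X.shape
    parent_sse = np.sum((y - y.mean()) ** 2)
    best = None
    for f in range(p):
        values = np.unique(X[:, f])
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            if len(left) < min_samples_leaf or len(right) < min_samples_leaf:
                continue
            sse = (np.sum((left - left.mean()) ** 2)
                   + np.sum((right - right.mean()) ** 2))
            reduction = parent_sse - sse
            if best is None or reduction > best[0] + 1e-12:
                best = (reduction, f, thr)
    return best


class TestFitTree:
    def test_single_sample_gives_single_leaf(self):
        tree = fit_tree([[3.0]], [7.5], ForestHyperparams())
        assert tree.n_nodes == 1
        assert tree.predict(np.array([[0.0]]))[0] == 7.5

    def test_hand_checked_depth_one_split(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        tree = fit_tree(X, y, ForestHyperparams(max_depth=1))
        assert tree.feature[0] == 0
        assert tree.threshold[0] == 1.5
        preds = tree.predict(np.array([[1.0], [2.0]]))
        np.testing.assert_array_equal(preds, [0.0, 10.0])

    def test_constant_target_collapses_to_leaf(self):
        X = np.arange(20, dtype=float).reshape(-1, 1)
        tree = fit_tree(X, np.full(20, 5.0), ForestHyperparams(max_depth=None))
        assert tree.n_nodes == 1

    def test_min_samples_leaf_respected(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        tree = fit_tree(X, y, ForestHyperparams(min_samples_leaf=7))
        leaves = tree.count[tree.feature == -1]
        assert leaves.min() >= 7

    def test_max_depth_one_matches_exhaustive_scan_on_100_datasets(self):
        """Depth-1 split must equal the brute-force (feature, threshold)
        SSE-reduction maximum, including tie-break, on 100 random sets."""
        rng = np.random.default_rng(12345)
        for trial in range(100):
            n = int(rng.integers(2, 51))
            p = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            tree = fit_tree(X, y, ForestHyperparams(max_depth=1), seed=trial)
            expected = exhaustive_best_split(X, y)
            if expected is None:
                assert tree.n_nodes == 1
                continue
            _, f, thr = expected
            assert tree.feature[0] == f
            assert tree.threshold[0] == pytest.approx(thr, abs=1e-12)

    def test_identical_x_column_values_make_leaf(self):
        X = np.ones((10, 2))
        y = np.arange(10.0)
        tree = fit_tree(X, y, ForestHyperparams())
        assert tree.n_nodes == 1
        assert tree.predict(np.array([[1.0, 1.0]]))[0] == pytest.approx(4.5)

    def test_empty_data_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_tree(np.empty((0, 2)), np.empty(0), ForestHyperparams())


class TestFitForest:
    def test_single_tree_without_bootstrap_equals_fit_tree(self, rng):
        X = rng.normal(size=(80, 3))
        y = rng.normal(size=80)
        params = ForestHyperparams(n_trees=1, max_depth=4)
        model = fit_forest(X, y, params, seed=3, bootstrap=False)
        # replicate the forest's internal per-tree seed stream
        tree_seed = int(np.random.default_rng(3).integers(0, 2**31 - 1))
        solo = fit_tree(X, y, params, seed=tree_seed)
        probe = rng.normal(size=(30, 3))
        np.testing.assert_array_equal(model.predict(probe), solo.predict(probe))

    def test_same_seed_reproduces_predictions(self, rng):
        X = rng.normal(size=(100, 4))
        y = rng.normal(size=100)
        params = ForestHyperparams(n_trees=20, max_depth=6, max_features=0.5)
        probe = rng.normal(size=(25, 4))
        a = fit_forest(X, y, params, seed=9).predict(probe)
        b = fit_forest(X, y, params, seed=9).predict(probe)
        np.testing.assert_array_equal(a, b)
        c = fit_forest(X, y, params, seed=10).predict(probe)
        assert not np.array_equal(a, c)

    def test_ensemble_reduces_heldout_error_on_smooth_target(self):
        """Bagging many trees should beat a single tree on noiseless
        linear data in nearly every seeded repetition."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-1, 1, size=(200, 3))
            w = np.array([1.0, -2.0, 0.5])
            y = X @ w
            X_test = rng.uniform(-1, 1, size=(200, 3))
            y_test = X_test @ w
            big = fit_forest(X, y, ForestHyperparams(n_trees=200, max_depth=6),
                             seed=seed)
            one = fit_forest(X, y, ForestHyperparams(n_trees=1, max_depth=6),
                             seed=seed)
            mse_big = np.mean((big.predict(X_test) - y_test) ** 2)
            mse_one = np.mean((one.predict(X_test) - y_test) ** 2)
            wins += mse_big < mse_one
        assert wins >= 18

    def test_matches_reference_trees_with_injected_resamples(self, rng):
        """With identical injected resamples and no feature subsampling,
        the forest must agree with averaged scikit-learn CART trees.

        Agreement is only well defined where no exact SSE-gain ties
        occur — scikit-learn breaks ties in randomized feature order.
        Ties arise from duplicated rows (hence resamples are drawn
        without replacement) and from tiny nodes where one row-partition
        is reachable through several features (hence a leaf size that
        keeps nodes large).  Inputs are made float32-representable
        because scikit-learn casts features to float32 internally before
        computing midpoint thresholds.  Within this regime the two
        implementations must agree to machine precision."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        X = rng.normal(size=(120, 3)).astype(np.float32).astype(float)
        y = rng.normal(size=120)
        indices = [rng.permutation(120)[:90] for _ in range(5)]
        params = ForestHyperparams(n_trees=5, max_depth=6,
                                   min_samples_leaf=8)
        model = fit_forest(X, y, params, seed=0, bootstrap_indices=indices)
        probe = rng.normal(size=(40, 3)).astype(np.float32).astype(float)
        ref = np.zeros(40)
        for take in indices:
            t = sklearn_tree.DecisionTreeRegressor(max_depth=6,
                                                   min_samples_leaf=8)
            t.fit(X[take], y[take])
            ref += t.predict(probe)
        np.testing.assert_allclose(model.predict(probe), ref / 5, atol=1e-10)

    def test_row_permutation_with_same_data_leaves_predictions_unchanged(
            self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        perm = rng.permutation(60)
        params = ForestHyperparams(n_trees=3, max_depth=5)
        probe = rng.normal(size=(20, 3))
        a = fit_forest(X, y, params, seed=1, bootstrap=False).predict(probe)
        b = fit_forest(X[perm], y[perm], params, seed=1,
                       bootstrap=False).predict(probe)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestPredict:
    def test_prediction_is_mean_of_tree_leaves(self, rng):
        X = np.array([[0.0], [1.0]])
        model_a = fit_forest(X, np.array([1.0, 1.0]),
                             ForestHyperparams(n_trees=1), bootstrap=False)
        model_b = fit_forest(X, np.array([3.0, 3.0]),
                             ForestHyperparams(n_trees=1), bootstrap=False)
        combined = ForestModel(trees=model_a.trees + model_b.trees,
                               params=ForestHyperparams(n_trees=2),
                               feature_names=("x0",), seed=0)
        assert combined.predict(np.array([[0.5]]))[0] == 2.0

    def test_predictions_stay_within_training_target_range(self, rng):
        X = rng.normal(size=(150, 4))
        y = rng.normal(size=150) * 10
        model = fit_forest(X, y, ForestHyperparams(n_trees=30, max_depth=8),
                           seed=2)
        preds = model.predict(rng.normal(size=(300, 4)) * 5)
        assert preds.min() >= y.min() and preds.max() <= y.max()

    def test_feature_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        model = fit_forest(X, rng.normal(size=30), ForestHyperparams(n_trees=2))
        with pytest.raises(ShapeMismatchError):
            predict(model, rng.normal(size=(5, 4)))

    def test_json_round_trip_preserves_predictions(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        model = fit_forest(X, y, ForestHyperparams(n_trees=4, max_depth=5),
                           seed=6, feature_names=("a", "b", "c"))
        back = ForestModel.from_json(model.to_json())
        probe = rng.normal(size=(20, 3))
        np.testing.assert_array_equal(model.predict(probe), back.predict(probe))
        assert back.feature_names == ("a", "b", "c")
        assert back.params == model.params
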