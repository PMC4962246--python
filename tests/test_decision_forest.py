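"""Decision Forest: tree induction, forest growth, prediction, persistence."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from erscreen import (
    LabeledDataset,
    TreeParams,
    classify,
    fit_forest,
    fit_tree,
    load_forest,
    predict_proba,
    save_forest,
)
from erscreen.decision_forest import _best_split

from conftest import make_dataset


def _enumerate_best_split(X, y, min_leaf):
    """Textbook oracle: weighted Gini over every (column, midpoint) candidate.

    Returns the minimising (col, threshold) under the tie-break lower
    column index, then lower threshold.
    """
    n, d = X.shape
    best = None
    for j in range(d):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = lo + (hi - lo) / 2.0
            if thr <= lo:
                thr = hi
            mask = X[:, j] <= thr
            nl, nr = int(mask.sum()), int((~mask).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            def gini(sub):
                p = sub.mean()
                return 2 * p * (1 - p)
            wg = (nl / n) * gini(y[mask]) + (nr / n) * gini(y[~mask])
            if (
                best is None
                or wg < best[0] - 1e-12
                or (abs(wg - best[0]) <= 1e-12 and (j, thr) < (best[1], best[2]))
            ):
                best = (wg, j, thr)
    return best


def _walk_internal_nodes(tree, X, names):
    """Yield (node, row_mask) for every internal node of *tree*."""
    col = {nm: j for j, nm in enumerate(names)}
    stack = [(tree.root, np.ones(len(X), dtype=bool))]
    while stack:
        node, mask = stack.pop()
        if node.is_leaf:
            continue
        yield node, mask
        j = col[node.split_descriptor]
        left = mask & (X[:, j] <= node.split_threshold)
        stack.append((node.left, left))
        stack.append((node.right, mask & ~left))


class TestFitTree:
    def test_perfectly_separable_single_split(self, separable_1d):
        tree = fit_tree(separable_1d)
        assert tree.used_descriptors == {"x"}
        assert 2.0 < tree.root.split_threshold < 8.0
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        assert {tree.root.left.probability, tree.root.right.probability} == {0.0, 1.0}

    def test_single_class_gives_degenerate_leaf(self):
        ds = make_dataset([[1.0], [2.0], [3.0]], labels=[1, 1, 1])
        tree = fit_tree(ds)
        assert tree.root.is_leaf
        assert tree.root.probability == 1.0
        assert tree.used_descriptors == frozenset()

    def test_empty_allowed_set_rejected(self, separable_1d):
        with pytest.raises(ValueError, match="empty"):
            fit_tree(separable_1d, allowed=set())

    def test_unlabeled_rejected(self):
        ds = make_dataset([[1.0], [2.0]])
        with pytest.raises(ValueError, match="label"):
            fit_tree(ds)

    def test_xor_needs_depth_two_and_fits_training(self, xor_dataset):
        params = TreeParams(max_depth=12, min_leaf_size=1, min_split_size=2)
        tree = fit_tree(xor_dataset, params=params)
        assert not tree.root.is_leaf
        assert not (tree.root.left.is_leaf and tree.root.right.is_leaf)
        cols = {nm: j for j, nm in enumerate(xor_dataset.descriptor_names)}
        p = tree.predict_proba(xor_dataset.values(), cols)
        acc = np.mean((p > 0.5).astype(int) == xor_dataset.label_array())
        assert acc == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_every_split_matches_enumeration_oracle(self, seed):
        """Greedy splits equal exhaustive (column, midpoint) search, incl. ties."""
        rng = np.random.default_rng(seed)
        n, d = 24, 3
        X = np.round(rng.normal(size=(n, d)), 1)  # rounding forces ties
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        ds = make_dataset(X, labels=y)
        params = TreeParams(max_depth=4, min_leaf_size=2, min_split_size=4)
        tree = fit_tree(ds, params=params)
        for node, mask in _walk_internal_nodes(tree, X, ds.descriptor_names):
            best = _enumerate_best_split(X[mask], y[mask].astype(float), 2)
            assert best is not None
            _, j, thr = best
            assert node.split_descriptor == ds.descriptor_names[j]
            assert node.split_threshold == pytest.approx(thr, abs=1e-12)

    def test_min_leaf_size_respected(self):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng.normal(size=(30, 4)), labels=rng.integers(0, 2, 30))
        params = TreeParams(max_depth=8, min_leaf_size=3, min_split_size=6)
        tree = fit_tree(ds, params=params)
        stack = [tree.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                assert node.n_total >= 3
            else:
                stack.extend([node.left, node.right])

    def test_sklearn_agrees_on_unique_best_split(self, separable_1d):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        clf = sklearn_tree.DecisionTreeClassifier(criterion="gini", random_state=0)
        clf.fit(separable_1d.values(), separable_1d.label_array())
        ours = fit_tree(separable_1d)
        assert ours.root.split_threshold == pytest.approx(clf.tree_.threshold[0])


class TestFitForest:
    def test_perfect_descriptor_gives_single_tree(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 10 + [1] * 10)
        X = rng.normal(size=(20, 5))
        X[:, 2] = y * 10.0 + rng.uniform(0, 1, size=20)  # perfect separator
        ds = make_dataset(X, labels=y)
        forest = fit_forest(ds)
        assert forest.n_trees == 1
        assert forest.training_trace == [0]

    def test_disjoint_subsets_on_noise_labels(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.normal(size=(40, 10)), labels=rng.integers(0, 2, 40))
        forest = fit_forest(ds, TreeParams(max_trees=5))
        assert forest.n_trees <= 5
        for i, a in enumerate(forest.trees):
            for b in forest.trees[i + 1:]:
                assert not (a.used_descriptors & b.used_descriptors)

    def test_trace_strictly_decreasing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 12))
        y = (X[:, 0] + 0.8 * X[:, 1] + rng.normal(0, 1.2, 60) > 0).astype(int)
        forest = fit_forest(make_dataset(X, labels=y), TreeParams(max_depth=3, max_trees=10))
        trace = forest.training_trace
        assert len(trace) == forest.n_trees
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_forest_no_worse_than_first_tree_on_training(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 15))
        y = (X[:, 0] + X[:, 3] + rng.normal(0, 1.5, 80) > 0).astype(int)
        ds = make_dataset(X, labels=y)
        forest = fit_forest(ds, TreeParams(max_depth=3))
        cols = {nm: j for j, nm in enumerate(ds.descriptor_names)}
        first_p = forest.trees[0].predict_proba(ds.values(), cols)
        first_err = int(np.sum((first_p > 0.5).astype(int) != y))
        forest_p = predict_proba(forest, ds)
        forest_err = int(np.sum((forest_p > 0.5).astype(int) != y))
        assert forest_err <= first_err

    def test_deterministic_refit(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 8))
        y = rng.integers(0, 2, 50)
        ds = make_dataset(X, labels=y)
        f1 = fit_forest(ds)
        f2 = fit_forest(ds)
        from erscreen.decision_forest import _node_to_dict
        assert [_node_to_dict(t.root) for t in f1.trees] == [
            _node_to_dict(t.root) for t in f2.trees
        ]


class TestPredict:
    def test_mean_of_member_probabilities(self, separable_1d):
        forest = fit_forest(separable_1d)
        cols = {"x": 0}
        member = np.array(
            [t.predict_proba(separable_1d.values(), cols) for t in forest.trees]
        )
        np.testing.assert_allclose(
            predict_proba(forest, separable_1d), member.mean(axis=0)
        )

    def test_pure_tree_on_its_training_data(self, separable_1d):
        forest = fit_forest(separable_1d)
        p = predict_proba(forest, separable_1d)
        assert set(np.unique(p)) <= {0.0, 1.0}

    def test_probability_within_member_range(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 10))
        y = (X[:, 0] + rng.normal(0, 1.0, 60) > 0).astype(int)
        ds = make_dataset(X, labels=y)
        forest = fit_forest(ds, TreeParams(max_depth=3))
        cols = {nm: j for j, nm in enumerate(ds.descriptor_names)}
        member = np.array([t.predict_proba(ds.values(), cols) for t in forest.trees])
        p = predict_proba(forest, ds)
        assert np.all(p >= member.min(axis=0) - 1e-15)
        assert np.all(p <= member.max(axis=0) + 1e-15)
        assert np.all((p >= 0) & (p <= 1))

    def test_missing_descriptor_named_in_error(self, separable_1d):
        forest = fit_forest(separable_1d)
        other = make_dataset([[1.0]], columns=["z"])
        with pytest.raises(ValueError, match="x"):
            predict_proba(forest, other)


class TestClassify:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, 0), (0.944, 1), (0.0, 0), (1.0, 1), (0.500001, 1)],
    )
    def test_boundary_is_nonbinder(self, p, expected):
        assert classify(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.2)
        with pytest.raises(ValueError):
            classify(-0.1)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_call_consistent_with_threshold(self, p):
        assert classify(p) == (1 if p > 0.5 else 0)


class TestPersistence:
    def test_round_trip_predictions_bit_exact(self, tmp_path):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 6))
        y = (X[:, 1] > 0).astype(int)
        ds = make_dataset(X, labels=y)
        forest = fit_forest(ds)
        path = tmp_path / "model.json"
        save_forest(forest, path)
        loaded = load_forest(path)
        np.testing.assert_array_equal(predict_proba(forest, ds), predict_proba(loaded, ds))
        assert loaded.training_trace == forest.training_trace
        assert loaded.hyperparams == forest.hyperparams
        # human-readable structured text
        doc = json.loads(path.read_text())
        assert doc["format"] == "erscreen-decision-forest"

    def test_params_invariants(self):
        with pytest.raises(ValueError):
            TreeParams(min_split_size=2, min_leaf_size=2)  # < 2*min_leaf
        with pytest.raises(ValueError):
            TreeParams(max_trees=0)
        with pytest.raises(ValueError):
            TreeParams(impurity="entropy")
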