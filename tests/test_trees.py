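import itertools

import numpy as np
import pytest

import thermoprofile as tp
from thermoprofile.trees import (
    CRITERIA,
    ForestConfig,
    TreeConfig,
    best_split,
    decision_stump,
    induce_tree,
    predict_forest,
    predict_tree,
    published_rule_predict,
    random_forest,
    split_criterion_value,
)

from conftest import make_table


def brute_force_best_value(x, y, criterion):
    """Exhaustive (attribute x midpoint) search, independent of the
    implementation's scan order and pruning."""
    best = -np.inf
    for j in range(x.shape[1]):
        vals = np.unique(x[:, j])
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            mask = x[:, j] <= thr
            lt = int(((y == 0) & mask).sum())
            lf = int(((y == 1) & mask).sum())
            rt = int((y == 0).sum()) - lt
            rf = int((y == 1).sum()) - lf
            best = max(best, split_criterion_value(criterion, lt, lf, rt, rf))
    return best


class TestInduction:
    def test_pure_input_single_leaf(self):
        t = make_table([[0.1], [0.2], [0.3]], labels=[0, 0, 0])
        model = induce_tree(t)
        assert model.root.is_leaf and model.root.klass == "T"

    def test_planted_threshold(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9])[:, None]
        y = (x[:, 0] > 0.5).astype(int)
        model = induce_tree(make_table(x, labels=y))
        assert model.depth() == 1
        assert 0.4 < model.root.threshold < 0.6
        preds = [predict_tree(model, {model.root.attribute: v}) for v in x[:, 0]]
        assert preds == ["F" if c else "T" for c in y]

    @pytest.mark.parametrize("criterion", CRITERIA)
    def test_root_split_matches_brute_force(self, criterion):
        rng = np.random.default_rng(hash(criterion) % 2**31)
        for _ in range(10):
            n, p = int(rng.integers(5, 31)), int(rng.integers(1, 6))
            x = rng.random((n, p)).round(1)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            found = best_split(x, y, [f"a{j}" for j in range(p)], criterion)
            expected = brute_force_best_value(x, y, criterion)
            if found is None:
                assert expected <= 0 or not np.isfinite(expected)
            else:
                assert found[2] == pytest.approx(expected, abs=1e-12)

    def test_empty_table_errors(self):
        import pandas as pd

        t = tp.FeatureTable(pd.DataFrame(columns=["count_A"], dtype=float))
        with pytest.raises(ValueError, match="empty"):
            induce_tree(t)


class TestStump:
    def test_consistent_with_tree_root(self):
        rng = np.random.default_rng(0)
        x = rng.random((30, 3))
        y = (x[:, 1] > 0.5).astype(int)
        t = make_table(x, labels=y)
        stump = decision_stump(t)
        full = induce_tree(t)
        assert stump.root.attribute == full.root.attribute
        assert stump.root.threshold == full.root.threshold

    def test_pure_data_leaf(self):
        t = make_table([[0.1], [0.9]], labels=[1, 1])
        assert decision_stump(t).root.is_leaf

    def test_xor_cap(self):
        # no single split separates an XOR pattern
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 3)
        y = np.array([0, 1, 1, 0] * 3)
        stump = decision_stump(make_table(x, labels=y))
        preds = np.array(
            [predict_tree(stump, dict(zip(stump.attributes, row))) == "F" for row in x]
        )
        assert (preds == y.astype(bool)).mean() <= 0.75


class TestPredict:
    def test_leaf_only(self):
        from thermoprofile.trees import TreeModel, TreeNode

        model = TreeModel(TreeNode(klass="F", counts=(0, 3)), TreeConfig(), [])
        assert predict_tree(model, {}) == "F"

    def test_boundary_goes_left(self):
        from thermoprofile.trees import TreeModel, TreeNode

        root = TreeNode(
            attribute="count_A",
            threshold=0.5,
            left=TreeNode(klass="T"),
            right=TreeNode(klass="F"),
        )
        model = TreeModel(root, TreeConfig(), ["count_A"])
        assert predict_tree(model, {"count_A": 0.5}) == "T"
        assert predict_tree(model, {"count_A": 0.7}) == "F"

    def test_missing_attribute_named(self):
        from thermoprofile.trees import TreeModel, TreeNode

        root = TreeNode(
            attribute="count_Q", threshold=0.5,
            left=TreeNode(klass="T"), right=TreeNode(klass="F"),
        )
        with pytest.raises(KeyError, match="count_Q"):
            predict_tree(TreeModel(root, TreeConfig(), ["count_Q"]), {"count_A": 1})


class TestForest:
    def planted(self, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.random((60, 4))
        y = (x[:, 0] > 0.5).astype(int)
        return make_table(x, labels=y), x, y

    def test_seed_determinism(self):
        t, x, y = self.planted()
        f1 = random_forest(t, ForestConfig(seed=5))
        f2 = random_forest(t, ForestConfig(seed=5))
        rows = [dict(zip(t.attributes, row)) for row in x]
        assert [predict_forest(f1, r) for r in rows] == [
            predict_forest(f2, r) for r in rows
        ]

    def test_forest_not_worse_than_single_tree(self):
        t, x, y = self.planted(1)
        forest = random_forest(t, ForestConfig(seed=2, n_trees=15))
        tree = induce_tree(t, TreeConfig(criterion="gini_index"))
        rows = [dict(zip(t.attributes, row)) for row in x]
        truth = np.where(y == 1, "F", "T")
        acc_forest = np.mean([predict_forest(forest, r) for r in rows] == truth)
        acc_tree = np.mean([predict_tree(tree, r) for r in rows] == truth)
        assert acc_forest >= acc_tree - 1e-12

    def test_degenerate_config_equals_plain_tree(self):
        t, x, y = self.planted(2)
        forest = random_forest(
            t, ForestConfig(seed=3, n_trees=1, bootstrap=False, mtry=4)
        )
        tree = induce_tree(t, TreeConfig(criterion="gini_index"))
        rows = [dict(zip(t.attributes, row)) for row in x]
        assert [predict_tree(forest.trees[0], r) for r in rows] == [
            predict_tree(tree, r) for r in rows
        ]


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        x = rng.random((20, 2))
        t = make_table(x, labels=(x[:, 0] > 0.5).astype(int))
        model = induce_tree(t)
        path = tmp_path / "tree.json"
        model.save(path)
        back = tp.TreeModel.load(path)
        rows = [dict(zip(t.attributes, row)) for row in x]
        assert [predict_tree(back, r) for r in rows] == [
            predict_tree(model, r) for r in rows
        ]


PUBLISHED_CASES = [
    ("stump_gainratio", {"freq_QN": 0.6}, "F"),
    ("stump_gainratio", {"freq_QN": 0.5}, "T"),
    ("parallel_2level", {"pct_E": 0.4, "freq_hydrophilic": 0.0}, "T"),
    ("parallel_2level", {"pct_E": 0.2, "freq_hydrophilic": 0.6}, "F"),
    ("parallel_2level", {"pct_E": 0.2, "freq_hydrophilic": 0.5}, "T"),
    ("forest_gini_fig1", {"freq_NQ": 0.04, "freq_NT": 0.9}, "T"),
    ("forest_gini_fig1", {"freq_NQ": 0.06, "freq_NT": 0.02}, "T"),
    ("forest_gini_fig1", {"freq_NQ": 0.06, "freq_NT": 0.05}, "undetermined"),
    ("tree_gainratio_fig2", {"freq_hydrophilic": 0.7, "pct_Q": 0.9}, "F"),
    ("tree_gainratio_fig2", {"freq_hydrophilic": 0.5, "pct_Q": 0.1}, "T"),
    ("tree_gainratio_fig2", {"freq_hydrophilic": 0.5, "pct_Q": 0.3}, "undetermined"),
]


class TestPublishedRules:
    @pytest.mark.parametrize("model_id,features,expected", PUBLISHED_CASES)
    def test_printed_branches(self, model_id, features, expected):
        assert published_rule_predict(model_id, features) == expected

    def test_total_over_three_outcomes(self):
        rng = np.random.default_rng(8)
        from thermoprofile.trees import PUBLISHED_MODEL_ATTRIBUTES, PUBLISHED_MODELS

        for model_id in PUBLISHED_MODELS:
            attrs = PUBLISHED_MODEL_ATTRIBUTES[model_id]
            for _ in range(50):
                features = {a: rng.random() for a in attrs}
                assert published_rule_predict(model_id, features) in (
                    "T", "F", "undetermined",
                )

    def test_missing_attribute_named(self):
        with pytest.raises(KeyError, match="freq_QN"):
            published_rule_predict("stump_gainratio", {"pct_Q": 0.1})

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown"):
            published_rule_predict("nope", {})
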