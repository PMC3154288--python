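import numpy as np
import pandas as pd
import pytest

import thermoprofile as tp
from thermoprofile.discretize import DiscretizationConfig, equal_frequency_codes
from thermoprofile.weighting import (
    METHODS,
    WeightingConfig,
    chi_squared_from_table,
    contingency,
    gini_gain_from_table,
    info_gain_from_table,
    normalize_weights,
    oner_errors,
    raw_weights,
    relief_weights,
    select_attributes,
    symmetric_uncertainty_from_table,
    weight,
    weighting_suite,
)

from conftest import make_table


def brute_force_relief(x, y):
    """O(n^2) reference Relief, written independently of the implementation."""
    n, p = x.shape
    span = x.max(axis=0) - x.min(axis=0)
    span[span == 0] = 1.0
    xn = (x - x.min(axis=0)) / span
    w = np.zeros(p)
    for i in range(n):
        best_hit, best_miss = None, None
        for j in range(n):
            if j == i:
                continue
            d = np.abs(xn[i] - xn[j]).sum()
            if y[j] == y[i]:
                if best_hit is None or d < best_hit[0]:
                    best_hit = (d, j)
            else:
                if best_miss is None or d < best_miss[0]:
                    best_miss = (d, j)
        w += np.abs(xn[i] - xn[best_miss[1]])
        if best_hit is not None:
            w -= np.abs(xn[i] - xn[best_hit[1]])
    return w / n


class TestContingencyMeasures:
    def test_perfect_balanced_predictor(self):
        table = np.array([[10, 0], [0, 10]], dtype=float)
        assert info_gain_from_table(table) == pytest.approx(1.0)
        assert symmetric_uncertainty_from_table(table) == pytest.approx(1.0)
        assert gini_gain_from_table(table) == pytest.approx(0.5)

    def test_independence_gives_zero(self):
        table = np.array([[25, 25], [25, 25]], dtype=float)
        assert info_gain_from_table(table) == pytest.approx(0.0, abs=1e-12)
        assert chi_squared_from_table(table) == pytest.approx(0.0)
        assert gini_gain_from_table(table) == pytest.approx(0.0, abs=1e-12)

    def test_chi_squared_worked_example(self):
        # expected counts all 20; 4 cells of (10^2)/20
        assert chi_squared_from_table(np.array([[30, 10], [10, 30]])) == pytest.approx(20.0)

    def test_correlation_of_complement_is_equal(self):
        rng = np.random.default_rng(0)
        a = rng.random(40)
        y = (rng.random(40) < 0.5).astype(int)
        t1 = make_table(a[:, None], labels=y)
        t2 = make_table(1 - a[:, None], labels=y)
        w1 = raw_weights(t1, "correlation")
        w2 = raw_weights(t2, "correlation")
        assert w1.iloc[0] == pytest.approx(w2.iloc[0])


class TestRelief:
    def test_one_dimensional_worked_example(self):
        # hits always 0.1 apart; misses 0.9/0.8/0.8/0.9 -> w = 0.85 - 0.10
        x = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        assert relief_weights(x, y)[0] == pytest.approx(0.75)
        assert brute_force_relief(x, y)[0] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(6, 21), rng.integers(1, 6)
        x = rng.random((n, p))
        y = np.array([0, 1] * n)[:n]
        assert np.allclose(relief_weights(x, y), brute_force_relief(x, y))


class TestOneR:
    def test_errors_per_attribute(self):
        # attribute 0 classifies perfectly; attribute 1 is noise
        x = np.array([[0.0, 0.3], [0.1, 0.9], [0.9, 0.2], [1.0, 0.8]])
        y = np.array([0, 0, 1, 1])
        errs = oner_errors(x, y, n_bins=2)
        assert errs[0] == pytest.approx(0.0)
        assert errs[1] > 0

    def test_leave_one_out_semantics(self):
        # attribute 0 equals the class; attribute 1 alternates independently
        y = np.array([0] * 6 + [1] * 6)
        x = np.column_stack([y.astype(float), np.tile([0.0, 1.0], 6)])
        t = make_table(x, labels=y)
        w = raw_weights(t, "rule_oner")
        # dropping the perfect attribute forces OneR onto the noisy one
        assert w.iloc[0] > w.iloc[1]
        assert w.iloc[1] == pytest.approx(0.0)

    def test_single_feature_fallback_mode(self):
        x = np.array([[0.0, 0.3], [0.1, 0.9], [0.9, 0.2], [1.0, 0.8]])
        t = make_table(x, labels=[0, 0, 1, 1])
        w = raw_weights(t, "rule_oner", WeightingConfig(oner_mode="single_feature"))
        assert w.iloc[0] == pytest.approx(1.0)


class TestNormalizeAndSelect:
    def test_scaling(self):
        wv = normalize_weights(pd.Series({"a": 2.0, "b": 1.0, "c": 0.0}))
        assert list(wv.weights) == [1.0, 0.5, 0.0]

    def test_all_zero_passthrough(self):
        wv = normalize_weights(pd.Series({"a": 0.0, "b": 0.0}))
        assert list(wv.weights) == [0.0, 0.0]

    def test_nan_errors_with_name(self):
        with pytest.raises(ValueError, match="bad"):
            normalize_weights(pd.Series({"ok": 1.0, "bad": np.nan}))

    def test_strict_threshold(self):
        wv = tp.WeightVector(
            "m",
            pd.Series({"a": 0.6, "b": 0.5, "c": 0.4}),
            pd.Series({"a": 0.6, "b": 0.5, "c": 0.4}),
        )
        sel = select_attributes(wv, 0.5)
        assert sel.selected == ["a"]
        assert sel.at_threshold == ["b"]

    def test_empty_selection_warns(self):
        wv = normalize_weights(pd.Series({"a": 0.0}), "m")
        with pytest.warns(UserWarning, match="no attribute"):
            sel = select_attributes(wv)
        assert sel.selected == []


class TestWeightDispatch:
    def make_planted(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        signal = y + rng.normal(0, 0.1, n)
        noise = rng.random((n, 2))
        return make_table(np.column_stack([signal, noise]), labels=y)

    @pytest.mark.parametrize("method", METHODS)
    def test_all_methods_rank_planted_first(self, method):
        t = self.make_planted()
        wv = weight(t, method)
        assert wv.weights.max() == pytest.approx(1.0)
        assert ((wv.weights >= 0) & (wv.weights <= 1)).all()
        if method not in ("deviation", "pca", "rule_oner"):
            assert wv.weights.idxmax() == t.attributes[0]

    def test_constant_attribute_zero_not_error(self):
        t = make_table(
            np.column_stack([np.linspace(0, 1, 10), np.full(10, 3.0)]),
            labels=[0] * 5 + [1] * 5,
        )
        for method in ("info_gain", "chi_squared", "correlation", "relief"):
            assert raw_weights(t, method).iloc[1] == pytest.approx(0.0)

    def test_single_class_errors(self):
        t = make_table(np.random.default_rng(0).random((8, 2)), labels=[0] * 8)
        with pytest.raises(ValueError):
            weight(t, "info_gain")

    def test_svm_direction_matches_sklearn(self):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        t = self.make_planted(n=40)
        ours = raw_weights(t, "svm").to_numpy()
        ref = sklearn_svm.SVC(kernel="linear", C=1.0).fit(
            t.matrix(), t.label_array()
        )
        theirs = np.abs(ref.coef_.ravel())
        cos = ours @ theirs / (np.linalg.norm(ours) * np.linalg.norm(theirs))
        assert cos > 0.95

    def test_pca_matches_numpy_loadings(self):
        rng = np.random.default_rng(1)
        x = rng.random((30, 3))
        t = make_table(x, labels=[0, 1] * 15)
        w = raw_weights(t, "pca").to_numpy()
        z = (x - x.mean(0)) / x.std(0)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        assert np.allclose(w, np.abs(vt[0]))

    def test_monotonicity_adding_class_copies(self):
        # appending exact class-copy attributes never demotes the original
        # perfect predictor below them
        y = np.array([0, 1] * 10)
        base = np.column_stack([y.astype(float), np.random.default_rng(2).random(20)])
        extended = np.column_stack([base, y.astype(float), y.astype(float)])
        for method in ("info_gain", "uncertainty", "gini", "correlation"):
            w_base = weight(make_table(base, labels=y), method).weights
            w_ext = weight(
                make_table(extended, labels=y, columns=["count_A", "count_C", "count_D", "count_E"]),
                method,
            ).weights
            assert w_base.iloc[0] == pytest.approx(1.0)
            assert w_ext.iloc[0] == pytest.approx(1.0)


class TestSuite:
    def test_eleven_vectors(self, default_pipeline):
        assert set(default_pipeline["vectors"]) == set(METHODS)
        assert default_pipeline["failures"] == {}

    def test_failure_isolation(self):
        t = make_table(np.random.default_rng(3).random((10, 2)))  # no labels
        vectors, selections, failures = weighting_suite(t)
        assert set(vectors) == {"deviation", "pca"}
        assert set(failures) == set(METHODS) - {"deviation", "pca"}


class TestDiscretize:
    def test_equal_frequency_codes(self):
        codes = equal_frequency_codes(np.arange(10, dtype=float), n_bins=2)
        assert list(codes) == [0] * 5 + [1] * 5

    def test_ties_collapse(self):
        codes = equal_frequency_codes(np.zeros(5), n_bins=4)
        assert set(codes) == {0}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DiscretizationConfig(n_bins=1)

    def test_contingency_counts(self):
        codes = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert contingency(codes, y).tolist() == [[1, 1], [1, 1]]
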