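"""Eleven attribute-weighting algorithms with [0,1] normalization and
threshold selection.

Raw weights per method (normalized afterwards by the maximum absolute
weight; an all-zero vector passes through unchanged):

* ``info_gain``    H(Y) - H(Y|A) on the equal-frequency-binned attribute (bits)
* ``gain_ratio``   information gain / H(A); zero when H(A) = 0
* ``chi_squared``  Pearson chi-squared of binned attribute x class
* ``gini``         Gini(Y) - sum_b p(b) Gini(Y|b)
* ``uncertainty``  symmetric uncertainty 2 IG / (H(A) + H(Y))
* ``relief``       deterministic full pass, k=1 nearest hit/miss under
                   Manhattan distance on range-normalized attributes,
                   w = mean(diff_miss - diff_hit)
* ``deviation``    SD(A) scaled by the attribute mean (min/max selectable)
* ``rule_oner``    error rate of the best one-rule classifier trained on the
                   table *without* the attribute (higher error => more
                   important); a single-feature accuracy fallback is provided
* ``svm``          |w_j| of a soft-margin linear SVM (hinge loss, C = 1),
                   solved in the dual with a box-constrained quasi-Newton
                   method; the bias is absorbed into an augmented constant
                   feature
* ``pca``          |loading_j| of the first principal component of the
                   z-standardized table
* ``correlation``  |point-biserial Pearson r| against the 0/1-encoded class

Selection keeps attributes with normalized weight strictly above the
threshold (default 0.5); weights exactly at the threshold are flagged in
the SelectionResult rather than selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .discretize import DiscretizationConfig, equal_frequency_codes
from .table import FeatureTable

METHODS = (
    "info_gain",
    "gain_ratio",
    "rule_oner",
    "deviation",
    "chi_squared",
    "gini",
    "uncertainty",
    "relief",
    "svm",
    "pca",
    "correlation",
)

_CLASS_CONDITIONAL = set(METHODS) - {"deviation", "pca"}


@dataclass
class WeightingConfig:
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    deviation_scaling: str = "average"  # average | minimum | maximum
    svm_C: float = 1.0
    svm_tol: float = 1e-4
    oner_mode: str = "leave_one_out"  # leave_one_out | single_feature


@dataclass
class WeightVector:
    method: str
    weights: pd.Series  # normalized to [0, 1]
    raw: pd.Series

    def __post_init__(self) -> None:
        w = self.weights
        if ((w < -1e-12) | (w > 1 + 1e-12)).any():
            raise ValueError("normalized weights must lie in [0, 1]")


@dataclass
class SelectionResult:
    method: str
    selected: list[str]
    threshold: float = 0.5
    at_threshold: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# entropy / contingency helpers


def _entropy(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _gini(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - (p**2).sum())


def contingency(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """bins x 2 count matrix of a coded attribute against the 0/1 class."""
    n_bins = int(codes.max()) + 1
    table = np.zeros((n_bins, 2), dtype=float)
    np.add.at(table, (codes, y), 1.0)
    return table


def info_gain_from_table(table: np.ndarray) -> float:
    class_counts = table.sum(axis=0)
    n = class_counts.sum()
    h_y = _entropy(class_counts)
    h_cond = sum(
        (row.sum() / n) * _entropy(row) for row in table if row.sum() > 0
    )
    return h_y - h_cond


def gain_ratio_from_table(table: np.ndarray) -> float:
    h_a = _entropy(table.sum(axis=1))
    if h_a == 0:
        return 0.0
    return info_gain_from_table(table) / h_a


def chi_squared_from_table(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    if n == 0:
        return 0.0
    keep_r = rows > 0
    keep_c = cols > 0
    sub = table[np.ix_(keep_r, keep_c)]
    expected = np.outer(rows[keep_r], cols[keep_c]) / n
    return float(((sub - expected) ** 2 / expected).sum())


def gini_gain_from_table(table: np.ndarray) -> float:
    class_counts = table.sum(axis=0)
    n = class_counts.sum()
    g_y = _gini(class_counts)
    g_cond = sum((row.sum() / n) * _gini(row) for row in table if row.sum() > 0)
    return g_y - g_cond


def symmetric_uncertainty_from_table(table: np.ndarray) -> float:
    h_a = _entropy(table.sum(axis=1))
    h_y = _entropy(table.sum(axis=0))
    if h_a + h_y == 0:
        return 0.0
    return 2.0 * info_gain_from_table(table) / (h_a + h_y)


_TABLE_MEASURES = {
    "info_gain": info_gain_from_table,
    "gain_ratio": gain_ratio_from_table,
    "chi_squared": chi_squared_from_table,
    "gini": gini_gain_from_table,
    "uncertainty": symmetric_uncertainty_from_table,
}


# ---------------------------------------------------------------------------
# per-method raw weights


def _binned_measure(x: np.ndarray, y: np.ndarray, method: str, n_bins: int) -> float:
    if np.ptp(x) == 0:
        return 0.0
    codes = equal_frequency_codes(x, n_bins)
    return _TABLE_MEASURES[method](contingency(codes, y))


def relief_weights(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic Relief: every example in turn, k=1 hit/miss.

    Distances are Manhattan over range-normalized attributes; per-attribute
    diff is |x - x'| / range (0 for a constant attribute). Nearest-neighbour
    ties break toward the lowest record index. An example whose class has no
    second member contributes no hit term.
    """
    n, p = x.shape
    rng_span = np.ptp(x, axis=0)
    safe = np.where(rng_span > 0, rng_span, 1.0)
    xn = (x - x.min(axis=0)) / safe
    xn[:, rng_span == 0] = 0.0
    dist = cdist(xn, xn, metric="cityblock")
    np.fill_diagonal(dist, np.inf)
    w = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        other = np.flatnonzero(y != y[i])
        if other.size == 0:
            raise ValueError("relief requires both classes present")
        miss = other[np.argmin(dist[i, other])]
        w += np.abs(xn[i] - xn[miss])
        same = same[same != i]
        if same.size:
            hit = same[np.argmin(dist[i, same])]
            w -= np.abs(xn[i] - xn[hit])
    return w / n


def oner_errors(x: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Training error of the one-rule classifier built on each attribute."""
    n, p = x.shape
    errs = np.empty(p)
    for j in range(p):
        codes = equal_frequency_codes(x[:, j], n_bins)
        table = contingency(codes, y)
        correct = table.max(axis=1).sum()
        errs[j] = 1.0 - correct / n
    return errs


def _oner_weights(x: np.ndarray, y: np.ndarray, config: WeightingConfig) -> np.ndarray:
    errs = oner_errors(x, y, config.discretization.n_bins)
    if config.oner_mode == "single_feature":
        return 1.0 - errs
    # leave-one-feature-out: the OneR model on the table without attribute j
    # picks the best remaining attribute, so its error is min over the others.
    order = np.argsort(errs)
    best, best_count = errs[order[0]], int((errs == errs[order[0]]).sum())
    second = errs[order[1]] if len(errs) > 1 else errs[order[0]]
    w = np.full_like(errs, best)
    if best_count == 1:
        w[order[0]] = second
    return w


def _svm_weights(x: np.ndarray, y: np.ndarray, config: WeightingConfig) -> np.ndarray:
    """|w| from the dual soft-margin linear SVM (bias via constant feature)."""
    ys = np.where(y == 1, 1.0, -1.0)
    xa = np.hstack([x, np.ones((x.shape[0], 1))])
    q = (ys[:, None] * xa) @ (ys[:, None] * xa).T

    def objective(alpha: np.ndarray) -> tuple[float, np.ndarray]:
        qa = q @ alpha
        return 0.5 * alpha @ qa - alpha.sum(), qa - 1.0

    n = x.shape[0]
    res = minimize(
        objective,
        np.zeros(n),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, config.svm_C)] * n,
        options={"maxiter": 2000, "ftol": config.svm_tol * 1e-3},
    )
    w = xa.T @ (res.x * ys)
    return np.abs(w[:-1])


def _pca_weights(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    w = np.zeros(x.shape[1])
    w[keep] = np.abs(vt[0])
    return w


def _correlation_weights(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / denom
    return np.abs(np.nan_to_num(r, nan=0.0))


def raw_weights(
    table: FeatureTable, method: str, config: WeightingConfig | None = None
) -> pd.Series:
    """Raw (pre-normalization) weights for one method."""
    if method not in METHODS:
        raise ValueError(f"unknown weighting method {method!r}")
    config = config or WeightingConfig()
    x = table.matrix()
    cols = table.attributes
    if method in _CLASS_CONDITIONAL:
        y = table.label_array()
        if len(np.unique(y)) < 2:
            raise ValueError(f"{method} weighting requires both classes present")
    else:
        y = None

    n_bins = config.discretization.n_bins
    if method in _TABLE_MEASURES:
        vals = np.array([_binned_measure(x[:, j], y, method, n_bins) for j in range(x.shape[1])])
    elif method == "relief":
        vals = relief_weights(x, y)
    elif method == "rule_oner":
        vals = _oner_weights(x, y, config)
    elif method == "deviation":
        sd = x.std(axis=0, ddof=1)
        scale = {
            "average": x.mean(axis=0),
            "minimum": x.min(axis=0),
            "maximum": x.max(axis=0),
        }[config.deviation_scaling]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(scale != 0, sd / scale, 0.0)
    elif method == "svm":
        vals = _svm_weights(x, y, config)
    elif method == "pca":
        vals = _pca_weights(x)
    elif method == "correlation":
        vals = _correlation_weights(x, y)
    return pd.Series(vals, index=cols)


def normalize_weights(raw: pd.Series, method: str = "") -> WeightVector:
    """Scale |raw| by its maximum into [0, 1]; all-zero passes through."""
    if raw.isna().any():
        bad = list(raw.index[raw.isna()])
        raise ValueError(f"NaN weight for attribute(s) {bad}")
    absraw = raw.abs()
    top = absraw.max()
    weights = absraw / top if top > 0 else absraw
    return WeightVector(method=method, weights=weights, raw=raw)


def weight(
    table: FeatureTable, method: str, config: WeightingConfig | None = None
) -> WeightVector:
    """Raw weights for one method, normalized into [0, 1]."""
    return normalize_weights(raw_weights(table, method, config), method)


def select_attributes(wv: WeightVector, threshold: float = 0.5) -> SelectionResult:
    """Attributes with normalized weight strictly above the threshold."""
    selected = list(wv.weights.index[wv.weights > threshold])
    at_threshold = list(wv.weights.index[wv.weights == threshold])
    if not selected:
        warnings.warn(
            f"{wv.method}: no attribute exceeds weight threshold {threshold}",
            UserWarning,
            stacklevel=2,
        )
    return SelectionResult(wv.method, selected, threshold, at_threshold)


def weighting_suite(
    table: FeatureTable,
    config: WeightingConfig | None = None,
    threshold: float = 0.5,
    methods: tuple[str, ...] = METHODS,
) -> tuple[dict[str, WeightVector], dict[str, SelectionResult], dict[str, str]]:
    """Run every weighting method; one method's failure aborts nothing.

    Returns (weight vectors, selections, failures keyed by method).
    """
    vectors: dict[str, WeightVector] = {}
    selections: dict[str, SelectionResult] = {}
    failures: dict[str, str] = {}
    for method in methods:
        try:
            wv = weight(table, method, config)
        except Exception as exc:  # noqa: BLE001 - suite isolates failures
            failures[method] = str(exc)
            continue
        vectors[method] = wv
        selections[method] = select_attributes(wv, threshold)
    return vectors, selections, failures
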