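"""Decision-tree induction and the published threshold-rule classifiers.

Induction is greedy top-down on numeric attributes with binary axis-aligned
splits. Candidate thresholds are midpoints between consecutive distinct
sorted values; ``x <= threshold`` goes left. Four split criteria are
supported: gain_ratio, info_gain, gini_index and accuracy (training-accuracy
gain). Ties between candidate splits break by schema/column order, then by
the lower threshold. Leaves predict the majority class; an exact tie
predicts T (the majority class of the study system). Pre-pruning only:
max_depth, min_leaf and a minimum criterion gain.

The published rule models encode, verbatim, the threshold rules of four
trees reported for this problem (a gain-ratio decision stump, a two-level
parallel tree, a gini random-forest tree and a gain-ratio tree). Branches
the source never spelled out return ``"undetermined"`` rather than a
guessed class. All thresholds are on the min-max normalized [0,1] scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .table import FeatureTable

CRITERIA = ("gain_ratio", "info_gain", "gini_index", "accuracy")


@dataclass
class TreeConfig:
    criterion: str = "gain_ratio"
    max_depth: int | None = None
    min_leaf: int = 1
    min_gain: float = 1e-3

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class TreeNode:
    # internal node fields
    attribute: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # leaf fields / bookkeeping (counts = (n_T, n_F) of training rows here)
    klass: str | None = None
    counts: tuple[int, int] = (0, 0)

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class": self.klass, "counts": list(self.counts)}
        return {
            "attribute": self.attribute,
            "threshold": self.threshold,
            "counts": list(self.counts),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "class" in d:
            return cls(klass=d["class"], counts=tuple(d["counts"]))
        return cls(
            attribute=d["attribute"],
            threshold=d["threshold"],
            counts=tuple(d["counts"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class TreeModel:
    root: TreeNode
    config: TreeConfig
    attributes: list[str]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "criterion": self.config.criterion,
                    "attributes": self.attributes,
                    "root": self.root.to_dict(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path: str | Path) -> "TreeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            TreeNode.from_dict(d["root"]), TreeConfig(criterion=d["criterion"]), d["attributes"]
        )

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def root_attribute(self) -> str | None:
        return self.root.attribute


# ---------------------------------------------------------------------------
# split criteria on (left_T, left_F, right_T, right_F)


def _entropy2(a: float, b: float) -> float:
    n = a + b
    if n == 0:
        return 0.0
    h = 0.0
    for c in (a, b):
        if c > 0:
            p = c / n
            h -= p * np.log2(p)
    return h


def _gini2(a: float, b: float) -> float:
    n = a + b
    if n == 0:
        return 0.0
    return 1.0 - (a / n) ** 2 - (b / n) ** 2


def split_criterion_value(
    criterion: str, lt: float, lf: float, rt: float, rf: float
) -> float:
    """Criterion gain of a binary split with child class counts."""
    n = lt + lf + rt + rf
    nl, nr = lt + lf, rt + rf
    if criterion in ("info_gain", "gain_ratio"):
        ig = _entropy2(lt + rt, lf + rf) - (nl / n) * _entropy2(lt, lf) - (
            nr / n
        ) * _entropy2(rt, rf)
        if criterion == "info_gain":
            return ig
        split_info = _entropy2(nl, nr)
        return ig / split_info if split_info > 0 else 0.0
    if criterion == "gini_index":
        return (
            _gini2(lt + rt, lf + rf)
            - (nl / n) * _gini2(lt, lf)
            - (nr / n) * _gini2(rt, rf)
        )
    # accuracy: gain in training accuracy of majority-class leaves
    before = max(lt + rt, lf + rf) / n
    after = (max(lt, lf) + max(rt, rf)) / n
    return after - before


def best_split(
    x: np.ndarray,
    y: np.ndarray,
    columns: list[str],
    criterion: str,
    min_leaf: int = 1,
    candidate_cols: np.ndarray | None = None,
) -> tuple[int, float, float] | None:
    """Best (column index, threshold, criterion value) or None.

    Scans columns in order and thresholds ascending, keeping the strictly
    best value, which implements the schema-order / lower-threshold
    tie-break.
    """
    n = len(y)
    n_t = int((y == 0).sum())
    n_f = n - n_t
    best_tuple: tuple[int, float, float] | None = None
    cols = range(x.shape[1]) if candidate_cols is None else candidate_cols
    for j in cols:
        order = np.argsort(x[:, j], kind="stable")
        xs, ys = x[order, j], y[order]
        cum_f = np.cumsum(ys)  # class F counts among first i+1 rows
        distinct = np.flatnonzero(np.diff(xs) > 0)
        for i in distinct:
            nl = i + 1
            if nl < min_leaf or n - nl < min_leaf:
                continue
            lf = int(cum_f[i])
            lt = nl - lf
            value = split_criterion_value(criterion, lt, lf, n_t - lt, n_f - lf)
            if best_tuple is None or value > best_tuple[2] + 1e-12:
                best_tuple = (int(j), float((xs[i] + xs[i + 1]) / 2.0), float(value))
    return best_tuple


def _grow(
    x: np.ndarray,
    y: np.ndarray,
    columns: list[str],
    config: TreeConfig,
    depth: int,
    rng: np.random.Generator | None = None,
    mtry: int | None = None,
) -> TreeNode:
    n_t = int((y == 0).sum())
    n_f = len(y) - n_t
    leaf_class = "F" if n_f > n_t else "T"  # tie -> T
    node = TreeNode(klass=leaf_class, counts=(n_t, n_f))
    if n_t == 0 or n_f == 0:
        return node
    if config.max_depth is not None and depth >= config.max_depth:
        return node
    candidate_cols = None
    if mtry is not None and mtry < x.shape[1]:
        candidate_cols = np.sort(rng.choice(x.shape[1], size=mtry, replace=False))
    found = best_split(x, y, columns, config.criterion, config.min_leaf, candidate_cols)
    if found is None or found[2] < config.min_gain:
        return node
    j, threshold, _ = found
    mask = x[:, j] <= threshold
    node.attribute = columns[j]
    node.threshold = threshold
    node.klass = None
    node.left = _grow(x[mask], y[mask], columns, config, depth + 1, rng, mtry)
    node.right = _grow(x[~mask], y[~mask], columns, config, depth + 1, rng, mtry)
    return node


def induce_tree(table: FeatureTable, config: TreeConfig | None = None) -> TreeModel:
    """Greedy top-down induction on the labelled table."""
    config = config or TreeConfig()
    if table.n_records == 0:
        raise ValueError("empty table")
    x = table.matrix()
    y = table.label_array()
    root = _grow(x, y, table.attributes, config, depth=0)
    return TreeModel(root, config, table.attributes)


def decision_stump(table: FeatureTable, criterion: str = "gain_ratio") -> TreeModel:
    """Depth-1 tree (single split)."""
    return induce_tree(table, TreeConfig(criterion=criterion, max_depth=1))


def predict_tree(model: TreeModel | TreeNode, features) -> str:
    """Deterministic descent; ``<=`` goes left. Mapping-like input."""
    node = model.root if isinstance(model, TreeModel) else model
    while not node.is_leaf:
        if node.attribute not in features:
            raise KeyError(f"missing attribute {node.attribute!r}")
        node = node.left if features[node.attribute] <= node.threshold else node.right
    return node.klass


def predict_table(model: TreeModel, table: FeatureTable) -> np.ndarray:
    rows = table.values
    return np.array(
        [predict_tree(model, rows.iloc[i]) for i in range(len(rows))], dtype=object
    )


# ---------------------------------------------------------------------------
# random forest


@dataclass
class ForestConfig:
    n_trees: int = 10
    seed: int = 0
    criterion: str = "gini_index"
    mtry: int | None = None  # default ceil(sqrt(p))
    bootstrap: bool = True
    max_depth: int | None = None
    min_leaf: int = 1
    min_gain: float = 1e-3


@dataclass
class ForestModel:
    trees: list[TreeModel]
    config: ForestConfig
    attributes: list[str] = field(default_factory=list)


def random_forest(table: FeatureTable, config: ForestConfig | None = None) -> ForestModel:
    """Seeded bagging of trees with per-split attribute subsampling."""
    config = config or ForestConfig()
    x = table.matrix()
    y = table.label_array()
    columns = table.attributes
    n, p = x.shape
    mtry = config.mtry if config.mtry is not None else int(np.ceil(np.sqrt(p)))
    rng = np.random.default_rng(config.seed)
    tree_config = TreeConfig(
        criterion=config.criterion,
        max_depth=config.max_depth,
        min_leaf=config.min_leaf,
        min_gain=config.min_gain,
    )
    trees = []
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n) if config.bootstrap else np.arange(n)
        root = _grow(x[idx], y[idx], columns, tree_config, 0, rng, mtry)
        trees.append(TreeModel(root, tree_config, columns))
    return ForestModel(trees, config, columns)


def predict_forest(model: ForestModel, features) -> str:
    votes = [predict_tree(t, features) for t in model.trees]
    n_f = sum(1 for v in votes if v == "F")
    return "F" if n_f > len(votes) - n_f else "T"  # tie -> T


# ---------------------------------------------------------------------------
# published rule models

PUBLISHED_MODELS = (
    "stump_gainratio",
    "parallel_2level",
    "forest_gini_fig1",
    "tree_gainratio_fig2",
)

PUBLISHED_MODEL_ATTRIBUTES = {
    "stump_gainratio": ["freq_QN"],
    "parallel_2level": ["pct_E", "freq_hydrophilic"],
    "forest_gini_fig1": ["freq_NQ", "freq_NT"],
    "tree_gainratio_fig2": ["freq_hydrophilic", "pct_Q"],
}


def published_rule_predict(model_id: str, features) -> str:
    """Apply one of the four published threshold-rule models.

    ``features`` maps attribute names to min-max normalized values. Returns
    "T", "F" or "undetermined" (for input regions whose outcome the source
    tree never printed). Raises KeyError naming any missing attribute.
    """
    if model_id not in PUBLISHED_MODELS:
        raise ValueError(f"unknown published model {model_id!r}")
    for name in PUBLISHED_MODEL_ATTRIBUTES[model_id]:
        if name not in features:
            raise KeyError(f"missing attribute {name!r}")

    if model_id == "stump_gainratio":
        # Gln-Asn dipeptide frequency > 0.500 -> thermostable
        return "F" if features["freq_QN"] > 0.500 else "T"

    if model_id == "parallel_2level":
        # Glu percentage > 0.322 -> T; otherwise hydrophilic freq > 0.550 -> F
        if features["pct_E"] > 0.322:
            return "T"
        return "F" if features["freq_hydrophilic"] > 0.550 else "T"

    if model_id == "forest_gini_fig1":
        # Asn-Gln freq <= 0.050 -> T; else Asn-Thr freq <= 0.029 -> T;
        # deeper branches (Gly-Gly, Asp-Pro) were not printed.
        if features["freq_NQ"] <= 0.050:
            return "T"
        return "T" if features["freq_NT"] <= 0.029 else "undetermined"

    # tree_gainratio_fig2: hydrophilic freq > 0.596 -> F;
    # < 0.596 with Gln percentage < 0.217 -> T; everything else unprinted.
    if features["freq_hydrophilic"] > 0.596:
        return "F"
    if features["freq_hydrophilic"] < 0.596 and features["pct_Q"] < 0.217:
        return "T"
    return "undetermined"
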