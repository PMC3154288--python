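"""Feed-forward and Elman networks, 10-fold cross-validation and the
stepwise (1 - p) attribute screen.

Both networks use logistic-sigmoid hidden layers, a 2-unit softmax output
and cross-entropy loss, trained by seeded mini-batch back-propagation with
optional early stopping on a held-out validation fraction.

The Elman network augments the first hidden layer with context units holding
that layer's previous activation. Feature vectors are static, so each
example is presented ``elman_context_steps`` times with the context zeroed
beforehand; gradients are back-propagated through the unrolled presentations
(shared weights). With one presentation and zero context weights the network
reduces exactly to the plain MLP.

Fold sizes follow a fixed rule: with n records and k folds, the first k-1
folds have size ceil(n/k) when (k-1)*ceil(n/k) < n (else floor(n/k)) and the
last fold takes the remainder — so 2057 records in 10 folds give nine folds
of 206 and one of 203.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .table import FeatureTable


@dataclass
class NetTopology:
    hidden_layers: list[int]

    def __post_init__(self) -> None:
        if not self.hidden_layers or any(h < 1 for h in self.hidden_layers):
            raise ValueError("need >= 1 hidden layer, all sizes >= 1")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.01
    epochs: int = 500
    seed: int = 0
    batch_size: int = 32
    val_fraction: float = 0.1
    patience: int = 50
    elman_context_steps: int = 2

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), 2))
    out[np.arange(len(y)), y] = 1.0
    return out


class MLPClassifier:
    """Dense feed-forward net: sigmoid hiddens, softmax output."""

    is_elman = False

    def __init__(self, n_inputs: int, topology: NetTopology, config: TrainingConfig):
        self.topology = topology
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        main_ss, ctx_ss = ss.spawn(2)
        rng = np.random.default_rng(main_ss)
        sizes = [n_inputs, *topology.hidden_layers, 2]
        self.weights = [
            rng.normal(0.0, 1.0 / math.sqrt(sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(s) for s in sizes[1:]]
        self._ctx_rng = np.random.default_rng(ctx_ss)
        self.loss_history: list[float] = []
        self.val_loss_history: list[float] = []

    # -- forward -------------------------------------------------------------
    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = _sigmoid(h @ w + b)
            acts.append(h)
        acts.append(_softmax(h @ self.weights[-1] + self.biases[-1]))
        return acts

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float))[-1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- backward ------------------------------------------------------------
    def _gradients(self, x: np.ndarray, t: np.ndarray):
        acts = self._forward(x)
        delta = (acts[-1] - t) / len(x)
        grads_w, grads_b = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w.append(acts[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * acts[layer] * (1 - acts[layer])
        return grads_w[::-1], grads_b[::-1]

    def _step(self, x: np.ndarray, t: np.ndarray) -> None:
        grads_w, grads_b = self._gradients(x, t)
        lr = self.config.learning_rate
        for w, gw in zip(self.weights, grads_w):
            w -= lr * gw
        for b, gb in zip(self.biases, grads_b):
            b -= lr * gb

    def _loss(self, x: np.ndarray, t: np.ndarray) -> float:
        p = self.predict_proba(x)
        return float(-(t * np.log(np.clip(p, 1e-12, None))).sum() / len(x))

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MLPClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        t = _one_hot(y)
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        n = len(x)
        n_val = int(round(cfg.val_fraction * n)) if cfg.val_fraction > 0 else 0
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        xtr, ttr = x[train_idx], t[train_idx]
        xval, tval = x[val_idx], t[val_idx]

        best_val = np.inf
        best_state = None
        stall = 0
        for _ in range(cfg.epochs):
            perm = rng.permutation(len(xtr))
            for start in range(0, len(xtr), cfg.batch_size):
                batch = perm[start : start + cfg.batch_size]
                self._step(xtr[batch], ttr[batch])
            loss = self._loss(xtr, ttr)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (loss={loss})")
            self.loss_history.append(loss)
            if n_val:
                vloss = self._loss(xval, tval)
                self.val_loss_history.append(vloss)
                if vloss < best_val - 1e-9:
                    best_val = vloss
                    best_state = (
                        [w.copy() for w in self.weights],
                        [b.copy() for b in self.biases],
                    )
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if best_state is not None:
            self.weights, self.biases = best_state
        return self


class ElmanClassifier(MLPClassifier):
    """Elman recurrent network over repeated presentations of each example.

    The first hidden layer receives a context copy of its own previous
    activation; the main weight stream matches the MLP's (the context
    weights draw from a separate stream), so zeroing the context weights
    with a single presentation reproduces the MLP exactly.
    """

    is_elman = True

    def __init__(self, n_inputs: int, topology: NetTopology, config: TrainingConfig):
        super().__init__(n_inputs, topology, config)
        h1 = topology.hidden_layers[0]
        self.context_weights = self._ctx_rng.normal(
            0.0, 1.0 / math.sqrt(h1), size=(h1, h1)
        )

    def _forward_steps(self, x: np.ndarray):
        """Unrolled first-layer activations plus upper-net activations."""
        steps = self.config.elman_context_steps
        w1, b1 = self.weights[0], self.biases[0]
        h = np.zeros((len(x), w1.shape[1]))
        h_steps = []
        for _ in range(steps):
            h = _sigmoid(x @ w1 + h @ self.context_weights + b1)
            h_steps.append(h)
        acts = [h]
        for w, b in zip(self.weights[1:-1], self.biases[1:-1]):
            acts.append(_sigmoid(acts[-1] @ w + b))
        acts.append(_softmax(acts[-1] @ self.weights[-1] + self.biases[-1]))
        return h_steps, acts

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        _, acts = self._forward_steps(np.asarray(x, dtype=float))
        return [x, *acts]

    def _gradients(self, x: np.ndarray, t: np.ndarray):
        h_steps, acts = self._forward_steps(x)
        n = len(x)
        delta = (acts[-1] - t) / n
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        grad_ctx = np.zeros_like(self.context_weights)
        # upper layers (acts[0] is the first-hidden activation)
        for layer in range(len(self.weights) - 1, 0, -1):
            grads_w[layer] = acts[layer - 1].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            delta = (delta @ self.weights[layer].T) * acts[layer - 1] * (1 - acts[layer - 1])
        # delta is now d loss / d pre-activation of the LAST presentation
        for step in range(len(h_steps) - 1, -1, -1):
            grads_w[0] += x.T @ delta
            grads_b[0] += delta.sum(axis=0)
            if step > 0:
                h_prev = h_steps[step - 1]
                grad_ctx += h_prev.T @ delta
                delta = (delta @ self.context_weights.T) * h_prev * (1 - h_prev)
        self._pending_ctx_grad = grad_ctx
        return grads_w, grads_b

    def _step(self, x: np.ndarray, t: np.ndarray) -> None:
        super()._step(x, t)
        self.context_weights -= self.config.learning_rate * self._pending_ctx_grad


def train_mlp(table: FeatureTable, topology: NetTopology, config: TrainingConfig) -> MLPClassifier:
    x = table.matrix()
    return MLPClassifier(x.shape[1], topology, config).fit(x, table.label_array())


def train_elman(table: FeatureTable, topology: NetTopology, config: TrainingConfig) -> ElmanClassifier:
    x = table.matrix()
    return ElmanClassifier(x.shape[1], topology, config).fit(x, table.label_array())


# ---------------------------------------------------------------------------
# cross-validation


def make_cv_folds(n: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffle, then the fixed fold-size rule described above."""
    if n < k:
        raise ValueError("need n >= k")
    ceil_size = -(-n // k)
    share = ceil_size if (k - 1) * ceil_size < n else n // k
    order = np.random.default_rng(seed).permutation(n)
    folds = [order[i * share : (i + 1) * share] for i in range(k - 1)]
    folds.append(order[(k - 1) * share :])
    return folds


@dataclass
class CVReport:
    """Per-fold accuracies in the layout of a 10-row + average table.

    ``accuracy_F`` is the thermostable-class accuracy, ``accuracy_T`` the
    mesostable-class accuracy; per-class values are NaN (and excluded from
    the averages) for folds holding a single class.
    """

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def averages(self) -> dict[str, float]:
        return {
            "accuracy_F": float(self.rows["accuracy_F"].mean()),
            "accuracy_T": float(self.rows["accuracy_T"].mean()),
            "overall": float(self.rows["overall"].mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        avg = self.averages
        out = self.rows.copy()
        out.loc["Average"] = [np.nan, np.nan, avg["accuracy_F"], avg["accuracy_T"], avg["overall"]]
        return out

    def to_dict(self) -> dict:
        return {
            "folds": self.rows.replace({np.nan: None}).to_dict(orient="records"),
            "averages": self.averages,
        }


def cross_validate(
    table: FeatureTable,
    model_factory,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """k-fold CV of ``model_factory(x_train, y_train) -> predict`` callables."""
    x = table.matrix()
    y = table.label_array()
    folds = make_cv_folds(len(x), k, seed)
    rows = []
    for fold in folds:
        mask = np.ones(len(x), dtype=bool)
        mask[fold] = False
        predict = model_factory(x[mask], y[mask])
        pred = np.asarray(predict(x[fold]))
        truth = y[fold]
        overall = float((pred == truth).mean())
        acc_f = float((pred[truth == 1] == 1).mean()) if (truth == 1).any() else np.nan
        acc_t = float((pred[truth == 0] == 0).mean()) if (truth == 0).any() else np.nan
        rows.append(
            {
                "train_n": int(mask.sum()),
                "test_n": int(len(fold)),
                "accuracy_F": acc_f,
                "accuracy_T": acc_t,
                "overall": overall,
            }
        )
    return CVReport(pd.DataFrame(rows, index=pd.RangeIndex(1, k + 1, name="run")))


def mlp_factory(topology: NetTopology, config: TrainingConfig):
    def factory(x: np.ndarray, y: np.ndarray):
        model = MLPClassifier(x.shape[1], topology, config).fit(x, y)
        return model.predict

    return factory


def elman_factory(topology: NetTopology, config: TrainingConfig):
    def factory(x: np.ndarray, y: np.ndarray):
        model = ElmanClassifier(x.shape[1], topology, config).fit(x, y)
        return model.predict

    return factory


# ---------------------------------------------------------------------------
# stepwise 1 - p screening


def stepwise_select(table: FeatureTable) -> pd.DataFrame:
    """Per-attribute one-way ANOVA F test against the binary class.

    Returns a frame with p_value, importance = 1 - p and the three-way label:
    important (> 0.95), marginal (0.90..0.95), unimportant (< 0.90).
    """
    y = table.label_array()
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("need >= 2 records per class")
    x = table.matrix()
    g0, g1 = x[y == 0], x[y == 1]
    pvals = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        a, b = g0[:, j], g1[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            pvals[j] = 1.0 if a[0] == b[0] else 0.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(a, b)
        pvals[j] = 1.0 if np.isnan(p) else p
    importance = 1.0 - pvals
    label = np.where(
        importance > 0.95,
        "important",
        np.where(importance >= 0.90, "marginal", "unimportant"),
    )
    return pd.DataFrame(
        {"p_value": pvals, "importance": importance, "label": label},
        index=pd.Index(table.attributes, name="attribute"),
    )
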