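"""Unsupervised clustering (k-means, k-medoids/PAM, support vector
clustering, EM Gaussian mixture) and the cluster-to-class evaluation.

All algorithms operate on the min-max normalized numeric matrix, take k=2 by
default, and produce a total assignment. The evaluation maps clusters onto
the T/F classes by the accuracy-maximizing permutation and reports the
mapped class counts and accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .table import FeatureTable


@dataclass
class ClusterConfig:
    k: int = 2
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-6
    em_covariance: str = "diagonal"  # diagonal | full
    svc_q: float = 1.0
    svc_C: float = 1.0
    svc_segment_samples: int = 10
    svc_max_n: int = 2000  # quadratic-programming size bound

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ClusterAssignment:
    record_ids: list[str]
    cluster_ids: np.ndarray  # int, one of 0..k-1 per record
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.record_ids) != len(self.cluster_ids):
            raise ValueError("one cluster id per record required")


@dataclass
class ConfusionTable:
    n_pred_T: int
    n_pred_F: int
    n_correct: int
    n: int
    accuracy: float
    mapping: dict[int, str]

    def to_dict(self) -> dict:
        return {
            "T": self.n_pred_T,
            "F": self.n_pred_F,
            "accuracy": self.accuracy,
            "mapping": {str(k): v for k, v in self.mapping.items()},
        }


def _as_matrix(table: FeatureTable | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, FeatureTable):
        return table.matrix(), table.record_ids
    x = np.asarray(table, dtype=float)
    return x, [str(i) for i in range(len(x))]


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    centers = [x[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min(cdist(x, np.asarray(centers), "sqeuclidean"), axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def kmeans(table: FeatureTable | np.ndarray, config: ClusterConfig | None = None) -> ClusterAssignment:
    """Lloyd iterations with k-means++ seeding; Euclidean distance."""
    config = config or ClusterConfig()
    x, ids = _as_matrix(table)
    if len(np.unique(x, axis=0)) < config.k:
        raise ValueError("fewer distinct rows than clusters")
    rng = np.random.default_rng(config.seed)
    centers = _kmeans_pp_init(x, config.k, rng)
    inertia_history: list[float] = []
    labels = np.zeros(len(x), dtype=int)
    for _ in range(config.max_iter):
        d2 = cdist(x, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        inertia_history.append(float(d2[np.arange(len(x)), labels].sum()))
        new_centers = centers.copy()
        for c in range(config.k):
            members = x[labels == c]
            if len(members):
                new_centers[c] = members.mean(axis=0)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < config.tol:
            break
    d2 = cdist(x, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    inertia_history.append(float(d2[np.arange(len(x)), labels].sum()))
    return ClusterAssignment(
        ids, labels, {"centroids": centers, "inertia_history": inertia_history}
    )


def kmedoids(table: FeatureTable | np.ndarray, config: ClusterConfig | None = None) -> ClusterAssignment:
    """PAM: greedy BUILD then best-improvement SWAP; medoids are data rows."""
    config = config or ClusterConfig()
    x, ids = _as_matrix(table)
    n = len(x)
    if len(np.unique(x, axis=0)) < config.k:
        raise ValueError("fewer distinct rows than clusters")
    dist = cdist(x, x)

    # BUILD: start from the most central point, then greedily add medoids
    medoids = [int(dist.sum(axis=1).argmin())]
    while len(medoids) < config.k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    cost_history = [cost(medoids)]
    improved = True
    while improved:
        improved = False
        best_cost = cost_history[-1]
        best_swap: tuple[int, int] | None = None
        non_medoids = [h for h in range(n) if h not in medoids]
        for mi, m in enumerate(medoids):
            others = [mm for mm in medoids if mm != m]
            base = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in non_medoids:
                c = float(np.minimum(base, dist[:, h]).sum())
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            cost_history.append(best_cost)
            improved = True
    labels = dist[:, medoids].argmin(axis=1)
    return ClusterAssignment(
        ids, labels, {"medoid_indices": list(medoids), "cost_history": cost_history}
    )


# ---------------------------------------------------------------------------
# support vector clustering


def _capped_simplex_projection(v: np.ndarray, cap: float) -> np.ndarray:
    """Euclidean projection onto {0 <= b <= cap, sum(b) = 1} by bisection."""
    lo = v.max() - 1.0 - cap
    hi = v.max()
    for _ in range(100):
        tau = 0.5 * (lo + hi)
        s = np.clip(v - tau, 0.0, cap).sum()
        if s > 1.0:
            lo = tau
        else:
            hi = tau
    return np.clip(v - 0.5 * (lo + hi), 0.0, cap)


def svc_cluster(table: FeatureTable | np.ndarray, config: ClusterConfig | None = None) -> ClusterAssignment:
    """Support vector clustering (Ben-Hur style).

    A minimal enclosing sphere of the Gaussian-kernel image (width q, soft
    margin C) is found by projected gradient on the dual; two points join the
    same cluster when every sampled point on their connecting segment lies
    inside the sphere. Bounded support vectors (outliers) and any components
    beyond the k largest are assigned to the nearest retained cluster and
    flagged.
    """
    config = config or ClusterConfig()
    x, ids = _as_matrix(table)
    n = len(x)
    if n > config.svc_max_n:
        raise ValueError(f"SVC limited to {config.svc_max_n} records (got {n})")
    q, cap = config.svc_q, max(config.svc_C, 1.0 / n + 1e-12)

    gram = x @ x.T
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2 * gram
    kmat = np.exp(-q * np.maximum(d2, 0.0))

    # minimise b'Kb over the capped simplex (K(x,x)=1 terms are constant)
    beta = np.full(n, 1.0 / n)
    lam = np.linalg.eigvalsh(kmat)[-1]
    step = 1.0 / (2.0 * lam + 1e-12)
    for _ in range(2000):
        grad = 2.0 * kmat @ beta
        new = _capped_simplex_projection(beta - step * grad, cap)
        if np.abs(new - beta).max() < config.tol:
            beta = new
            break
        beta = new

    bkb = float(beta @ kmat @ beta)
    kb = kmat @ beta  # sum_i beta_i K(x_i, x_j)
    r2_all = 1.0 - 2.0 * kb + bkb
    bounded = beta >= cap - 1e-8
    on_sphere = (beta > 1e-8) & ~bounded
    radius2 = float(r2_all[on_sphere].max()) if on_sphere.any() else float(r2_all.max())
    radius2 += 1e-9

    inside = np.flatnonzero(~bounded)
    sv = np.flatnonzero(beta > 1e-8)
    lambdas = np.linspace(0.0, 1.0, config.svc_segment_samples)

    # adjacency via the linear Gram matrix only: a segment point
    # z = t x_i + (1-t) x_j has |z - x_s|^2 expressible in dot products.
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    beta_sv = beta[sv]
    for ii, i in enumerate(inside):
        for j in inside[ii + 1 :]:
            if find(i) == find(j):
                continue
            zz = (
                lambdas**2 * sq[i]
                + (1 - lambdas) ** 2 * sq[j]
                + 2 * lambdas * (1 - lambdas) * gram[i, j]
            )
            zs = lambdas[:, None] * gram[i, sv] + (1 - lambdas)[:, None] * gram[j, sv]
            dz = zz[:, None] + sq[sv][None, :] - 2 * zs
            kz = np.exp(-q * np.maximum(dz, 0.0)) @ beta_sv
            r2_seg = 1.0 - 2.0 * kz + bkb
            if (r2_seg <= radius2).all():
                union(i, j)

    roots = np.array([find(i) for i in inside])
    comp_ids, comp_sizes = np.unique(roots, return_counts=True)
    order = np.argsort(-comp_sizes, kind="stable")
    kept = comp_ids[order[: config.k]]
    labels = np.full(n, -1, dtype=int)
    for c, root in enumerate(kept):
        labels[inside[roots == root]] = c

    flagged = np.flatnonzero(labels < 0)
    for i in flagged:
        best_c, best_d = 0, np.inf
        for c in range(len(kept)):
            members = np.flatnonzero(labels == c)
            if members.size:
                d = d2[i, members].min()
                if d < best_d:
                    best_c, best_d = c, d
        labels[i] = best_c
    return ClusterAssignment(
        ids,
        labels,
        {
            "n_components": len(comp_ids),
            "flagged": [ids[i] for i in flagged],
            "support_vector_indices": list(map(int, sv)),
            "radius2": radius2,
        },
    )


# ---------------------------------------------------------------------------
# EM Gaussian mixture


class _Degenerate(Exception):
    """Internal: an EM component lost all its responsibility mass."""


def _log_gauss_diag(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (
        np.log(2 * np.pi * var).sum() + (((x - mean) ** 2) / var).sum(axis=1)
    )


def em_cluster(table: FeatureTable | np.ndarray, config: ClusterConfig | None = None) -> ClusterAssignment:
    """Diagonal-covariance Gaussian mixture fitted by EM.

    Initialized from a k-means run with the same seed; iterates until the
    log-likelihood gain drops below ``tol``; a degenerate (empty) component
    triggers one re-seeded restart before erroring. Variances floored at 1e-6.
    """
    config = config or ClusterConfig()
    x, ids = _as_matrix(table)
    n, p = x.shape
    if n < config.k:
        raise ValueError("need at least k rows")
    if config.em_covariance != "diagonal":
        raise NotImplementedError("only diagonal covariance is implemented")

    def run(seed: int) -> tuple[np.ndarray, dict]:
        init = kmeans(x, ClusterConfig(k=config.k, seed=seed, max_iter=config.max_iter))
        means = np.asarray(init.summary["centroids"], dtype=float)
        variances = np.empty((config.k, p))
        weights = np.empty(config.k)
        for c in range(config.k):
            members = x[init.cluster_ids == c]
            if len(members) == 0:
                raise _Degenerate()
            variances[c] = np.maximum(members.var(axis=0), 1e-6)
            weights[c] = len(members) / n
        loglik_history: list[float] = []
        resp = np.empty((n, config.k))
        for _ in range(config.max_iter):
            log_p = np.stack(
                [
                    np.log(weights[c]) + _log_gauss_diag(x, means[c], variances[c])
                    for c in range(config.k)
                ],
                axis=1,
            )
            m = log_p.max(axis=1, keepdims=True)
            log_norm = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
            loglik = float(log_norm.sum())
            resp = np.exp(log_p - log_norm[:, None])
            if loglik_history and loglik - loglik_history[-1] < config.tol:
                loglik_history.append(loglik)
                break
            loglik_history.append(loglik)
            nk = resp.sum(axis=0)
            if (nk < 1e-10).any():
                raise _Degenerate()
            weights = nk / n
            means = (resp.T @ x) / nk[:, None]
            for c in range(config.k):
                diff2 = (x - means[c]) ** 2
                variances[c] = np.maximum((resp[:, c] @ diff2) / nk[c], 1e-6)
        labels = resp.argmax(axis=1)
        return labels, {
            "means": means,
            "variances": variances,
            "mixing_weights": weights,
            "loglik_history": loglik_history,
        }

    try:
        labels, summary = run(config.seed)
    except _Degenerate:
        try:
            labels, summary = run(config.seed + 1)
        except _Degenerate as exc:
            raise RuntimeError("EM produced an empty component twice") from exc
    return ClusterAssignment(ids, labels, summary)


CLUSTERERS = {
    "kmeans": kmeans,
    "kmedoids": kmedoids,
    "svc": svc_cluster,
    "em": em_cluster,
}


def evaluate_clusters(assignment: ClusterAssignment, labels) -> ConfusionTable:
    """Best-of-two-permutations mapping of clusters onto the T/F classes."""
    y = np.asarray([str(v) for v in labels])
    if set(np.unique(y)) - {"T", "F"}:
        raise ValueError("labels must be T/F")
    if len(y) != len(assignment.cluster_ids):
        raise ValueError("labels must cover every record")
    cid = assignment.cluster_ids
    best: ConfusionTable | None = None
    for mapping in ({0: "T", 1: "F"}, {0: "F", 1: "T"}):
        mapped = np.array([mapping.get(int(c), "T") for c in cid])
        correct = int((mapped == y).sum())
        ct = ConfusionTable(
            n_pred_T=int((mapped == "T").sum()),
            n_pred_F=int((mapped == "F").sum()),
            n_correct=correct,
            n=len(y),
            accuracy=correct / len(y),
            mapping=mapping,
        )
        if best is None or ct.accuracy > best.accuracy:
            best = ct
    return best
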