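"""From-scratch supervised learners: KNN, polynomial-kernel SVM, Gini tree.

All three are implemented directly on numpy — no learning library is used —
because the learners themselves, not their surroundings, are the point:

* K-nearest neighbours with Euclidean distance and majority vote; vote ties
  break toward the class of the nearest neighbour, then the lower class id.
* One-vs-rest soft-margin SVM with the polynomial kernel
  ``K(a, b) = (gamma * <a, b> + r) ** degree`` trained by simplified
  SMO (pairwise dual coordinate updates).
* Binary decision tree grown by exhaustive Gini-impurity split search under
  a total node budget (internal + leaf nodes).

KNN and the SVM standardize features with train-set statistics; the tree is
scale-invariant and uses raw features.  Models serialize to a versioned JSON
document.
"""

from __future__ import annotations

import heapq
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "euclidean_distance",
    "poly_kernel",
    "gini",
    "KernelParams",
    "KNNModel",
    "knn_fit",
    "knn_predict",
    "knn_scores",
    "SVMModel",
    "svm_fit",
    "svm_predict",
    "svm_decision",
    "TreeModel",
    "dt_fit",
    "dt_predict",
    "dt_proba",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance sqrt(sum (y_i - x_i)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((y - x) ** 2)))


@dataclass(frozen=True)
class _Scaler:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(X.mean(axis=0), sd)

    @classmethod
    def identity(cls, n_features: int) -> "_Scaler":
        return cls(np.zeros(n_features), np.ones(n_features))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def _as_queries(query: np.ndarray, n_features: int) -> tuple[np.ndarray, bool]:
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != n_features:
        raise ValueError(f"query has {q.shape[1]} features, model expects {n_features}")
    return q, np.asarray(query).ndim == 1


# ---------------------------------------------------------------- KNN


@dataclass
class KNNModel:
    """Fitted nearest-neighbour classifier (stores standardized vectors)."""

    X: np.ndarray
    y: np.ndarray
    k: int
    classes: np.ndarray
    scaler: _Scaler

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def knn_fit(
    features: np.ndarray, labels: np.ndarray, k: int = 4, standardize: bool = True
) -> KNNModel:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a non-empty 2-D array")
    if X.shape[0] != y.size:
        raise ValueError("features and labels must align")
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"K must satisfy 1 <= K <= {X.shape[0]}, got {k}")
    scaler = _Scaler.fit(X) if standardize else _Scaler.identity(X.shape[1])
    return KNNModel(scaler.transform(X), y, k, np.unique(y), scaler)


def _knn_votes(model: KNNModel, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vote counts per class (n_queries, n_classes) and neighbour order."""
    diff = queries[:, None, :] - model.X[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    order = np.argsort(dist, axis=1, kind="stable")[:, : model.k]
    votes = np.zeros((queries.shape[0], model.classes.size))
    class_index = {c: i for i, c in enumerate(model.classes)}
    for row, nbrs in enumerate(order):
        for t in nbrs:
            votes[row, class_index[model.y[t]]] += 1
    return votes, order


def knn_predict(model: KNNModel, query: np.ndarray) -> int | np.ndarray:
    """Majority label among the K nearest training vectors.

    Vote ties break toward the tied class containing the nearest neighbour;
    remaining ties toward the lower class id (guaranteed by neighbour order
    being stable in training index).
    """
    q, single = _as_queries(query, model.n_features)
    votes, order = _knn_votes(model, model.scaler.transform(q))
    out = np.empty(q.shape[0], dtype=int)
    for row in range(q.shape[0]):
        top = votes[row].max()
        tied = set(model.classes[votes[row] == top])
        if len(tied) == 1:
            out[row] = tied.pop()
        else:
            for t in order[row]:  # nearest first
                if model.y[t] in tied:
                    out[row] = model.y[t]
                    break
    return int(out[0]) if single else out


def knn_scores(model: KNNModel, query: np.ndarray) -> np.ndarray:
    """Per-class vote fractions, shape (n_queries, n_classes)."""
    q, single = _as_queries(query, model.n_features)
    votes, _ = _knn_votes(model, model.scaler.transform(q))
    scores = votes / model.k
    return scores[0] if single else scores


# ---------------------------------------------------------------- SVM


@dataclass(frozen=True)
class KernelParams:
    """Polynomial kernel parameters ``(gamma * <a, b> + r) ** degree``."""

    gamma: float
    r: float = 1.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if int(self.degree) != self.degree or self.degree < 1:
            raise ValueError("degree must be an integer >= 1")


def poly_kernel(a: np.ndarray, b: np.ndarray, params: KernelParams) -> float | np.ndarray:
    """Polynomial kernel; accepts vectors or stacked row matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError("kernel arguments must share the feature dimension")
    inner = a @ b.T if a.ndim > 1 or b.ndim > 1 else float(a @ b)
    return (params.gamma * inner + params.r) ** params.degree


@dataclass
class _BinarySVM:
    """One binary one-vs-rest machine in dual form."""

    dual_coef: np.ndarray  # alpha_i * y_i over support vectors
    support_vectors: np.ndarray
    bias: float
    converged: bool = True


@dataclass
class SVMModel:
    classes: np.ndarray
    machines: list[_BinarySVM]
    C: float
    kernel: KernelParams
    scaler: _Scaler
    n_features: int = 0


def _smo(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float,
    max_passes: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, bool]:
    """Simplified SMO on a precomputed kernel matrix; y in {-1, +1}.

    Pairwise updates keep 0 <= alpha <= C and sum(alpha * y) = 0 exact.
    The margin vector F_i = sum_j alpha_j y_j K_ij + b is maintained
    incrementally.  Iteration stops when a sweep leaves every KKT condition
    satisfied to ``tol``, or when the dual objective (monotone under exact
    pairwise updates) stalls for three consecutive sweeps, or at the
    ``max_passes`` sweep cap (reported as non-convergence).
    """
    n = y.size
    alpha = np.zeros(n)
    b = 0.0
    F = np.full(n, b)  # decision values, updated incrementally
    converged = False
    stalled_sweeps = 0
    objective = 0.0
    for _ in range(max_passes):
        changed = 0
        for i in range(n):
            Ei = F[i] - y[i]
            if not (
                (y[i] * Ei < -tol and alpha[i] < C)
                or (y[i] * Ei > tol and alpha[i] > 0)
            ):
                continue
            j = int(rng.integers(n - 1))
            j += j >= i
            Ej = F[j] - y[j]
            ai_old, aj_old = alpha[i], alpha[j]
            if y[i] == y[j]:
                L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
            else:
                L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
            if L == H:
                continue
            eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
            if eta >= 0:
                continue
            aj = float(np.clip(aj_old - y[j] * (Ei - Ej) / eta, L, H))
            if abs(aj - aj_old) < 1e-7:
                continue
            ai = ai_old + y[i] * y[j] * (aj_old - aj)
            alpha[i], alpha[j] = ai, aj
            dai, daj = ai - ai_old, aj - aj_old
            b1 = b - Ei - y[i] * dai * K[i, i] - y[j] * daj * K[i, j]
            b2 = b - Ej - y[i] * dai * K[i, j] - y[j] * daj * K[j, j]
            if 0 < ai < C:
                new_b = b1
            elif 0 < aj < C:
                new_b = b2
            else:
                new_b = (b1 + b2) / 2.0
            F += y[i] * dai * K[:, i] + y[j] * daj * K[:, j] + (new_b - b)
            b = new_b
            changed += 1
        if changed == 0:
            converged = True
            break
        ay = alpha * y
        new_objective = float(alpha.sum() - 0.5 * ay @ K @ ay)
        gain = new_objective - objective
        objective = new_objective
        stalled_sweeps = stalled_sweeps + 1 if gain < 1e-7 * max(1.0, abs(objective)) else 0
        if stalled_sweeps >= 3:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SMO did not converge within {max_passes} sweeps", RuntimeWarning
        )
    return alpha, b, converged


def svm_fit(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 14.5,
    params: KernelParams | None = None,
    tol: float = 1e-4,
    max_passes: int = 10_000,
    seed: int = 4,
    standardize: bool = True,
) -> SVMModel:
    """Train one one-vs-rest soft-margin machine per class by simplified SMO."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] == 0:
        raise ValueError("training set must be non-empty with aligned labels")
    if C <= 0:
        raise ValueError("C must be > 0")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("SVM training requires at least two classes")
    if params is None:
        params = KernelParams(gamma=1.0 / X.shape[1])
    scaler = _Scaler.fit(X) if standardize else _Scaler.identity(X.shape[1])
    Z = scaler.transform(X)
    K = poly_kernel(Z, Z, params)
    rng = np.random.default_rng(seed)
    machines = []
    for c in classes:
        yc = np.where(y == c, 1.0, -1.0)
        alpha, b, converged = _smo(K, yc, C, tol, max_passes, rng)
        support = alpha > 1e-10
        machines.append(
            _BinarySVM(
                dual_coef=(alpha * yc)[support],
                support_vectors=Z[support],
                bias=b,
                converged=converged,
            )
        )
    return SVMModel(classes, machines, C, params, scaler, n_features=X.shape[1])


def svm_decision(model: SVMModel, query: np.ndarray) -> np.ndarray:
    """One-vs-rest decision values, shape (n_queries, n_classes)."""
    q, single = _as_queries(query, model.n_features)
    Z = model.scaler.transform(q)
    cols = []
    for machine in model.machines:
        if machine.support_vectors.size:
            Kq = poly_kernel(Z, machine.support_vectors, model.kernel)
            cols.append(Kq @ machine.dual_coef + machine.bias)
        else:
            cols.append(np.full(Z.shape[0], machine.bias))
    values = np.column_stack(cols)
    return values[0] if single else values


def svm_predict(model: SVMModel, query: np.ndarray) -> int | np.ndarray:
    """Class with the largest decision value; ties to the lowest class id."""
    q, single = _as_queries(query, model.n_features)
    values = np.atleast_2d(svm_decision(model, q))
    out = model.classes[np.argmax(values, axis=1)]
    return int(out[0]) if single else out


# ---------------------------------------------------------------- decision tree


def gini(class_proportions: np.ndarray) -> float:
    """Gini diversity index 1 - sum p_i^2 of a class distribution."""
    p = np.asarray(class_proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    return float(1.0 - np.sum(p**2))


def _node_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes).astype(float)


def _gini_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    return 1.0 - float(np.sum((counts / n) ** 2)) if n else 0.0


def _best_split(
    X: np.ndarray, y: np.ndarray, n_classes: int
) -> tuple[int, float, float] | None:
    """Exhaustive search over features and midpoint thresholds.

    Returns ``(feature, threshold, weighted_child_gini)`` of the best split
    (ties: lower feature index, then lower threshold), or None when no split
    separates the node.
    """
    n = y.size
    best: tuple[float, int, float] | None = None
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys = X[order, f], y[order]
        # cumulative class counts at each prefix
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        left = np.cumsum(onehot, axis=0)
        total = left[-1]
        cut = np.flatnonzero(xs[:-1] < xs[1:])  # split between distinct values
        if cut.size == 0:
            continue
        nl = (cut + 1).astype(float)
        nr = n - nl
        gl = 1.0 - np.sum((left[cut] / nl[:, None]) ** 2, axis=1)
        gr = 1.0 - np.sum(((total - left[cut]) / nr[:, None]) ** 2, axis=1)
        weighted = (nl * gl + nr * gr) / n
        k = int(np.argmin(weighted))
        threshold = 0.5 * (xs[cut[k]] + xs[cut[k] + 1])
        cand = (float(weighted[k]), f, float(threshold))
        if best is None or cand[0] < best[0] - 1e-15:
            best = cand
    if best is None:
        return None
    w, f, thr = best
    return f, thr, w


@dataclass
class TreeModel:
    """Binary Gini tree as a flat node list.

    Each node dict has ``feature``/``threshold``/``left``/``right`` for
    internal nodes or ``class_id``/``proportions`` for leaves.
    """

    nodes: list[dict[str, Any]]
    n_classes: int
    max_nodes: int = 10

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def dt_fit(features: np.ndarray, labels: np.ndarray, max_nodes: int = 10) -> TreeModel:
    """Grow a Gini tree best-first under a total node budget.

    Growth stops when the budget cannot afford another split (each split
    adds two nodes), every leaf is pure, or no split improves the weighted
    child impurity.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[0] != y.size:
        raise ValueError("training set must be non-empty with aligned labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature values must be finite")
    if max_nodes < 1:
        raise ValueError("max_nodes must be >= 1")
    n_classes = int(y.max()) + 1

    def leaf(idx: np.ndarray) -> dict[str, Any]:
        counts = _node_counts(y[idx], n_classes)
        return {
            "class_id": int(np.argmax(counts)),
            "proportions": (counts / counts.sum()).tolist(),
        }

    nodes: list[dict[str, Any]] = [leaf(np.arange(y.size))]
    membership = {0: np.arange(y.size)}
    # max-heap of candidate splits: (-impurity decrease, insertion order, ...)
    heap: list[tuple[float, int, int, int, float]] = []
    counter = 0

    def push_candidate(node_id: int) -> None:
        nonlocal counter
        idx = membership[node_id]
        counts = _node_counts(y[idx], n_classes)
        parent = _gini_from_counts(counts)
        if parent == 0.0:
            return
        found = _best_split(X[idx], y[idx], n_classes)
        if found is None:
            return
        f, thr, weighted = found
        decrease = parent - weighted
        if decrease <= 1e-12:
            return
        heapq.heappush(heap, (-decrease, counter, node_id, f, thr))
        counter += 1

    push_candidate(0)
    while heap and len(nodes) + 2 <= max_nodes:
        _, _, node_id, f, thr = heapq.heappop(heap)
        idx = membership.pop(node_id)
        mask = X[idx, f] <= thr
        left_idx, right_idx = idx[mask], idx[~mask]
        left_id, right_id = len(nodes), len(nodes) + 1
        nodes.append(leaf(left_idx))
        nodes.append(leaf(right_idx))
        nodes[node_id] = {
            "feature": int(f),
            "threshold": float(thr),
            "left": left_id,
            "right": right_id,
        }
        membership[left_id] = left_idx
        membership[right_id] = right_idx
        push_candidate(left_id)
        push_candidate(right_id)
    return TreeModel(nodes, n_classes, max_nodes)


def _tree_leaf(model: TreeModel, x: np.ndarray) -> dict[str, Any]:
    node = model.nodes[0]
    while "feature" in node:
        node = model.nodes[
            node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
        ]
    return node


def dt_predict(model: TreeModel, query: np.ndarray) -> int | np.ndarray:
    q = np.atleast_2d(np.asarray(query, dtype=float))
    out = np.array([_tree_leaf(model, row)["class_id"] for row in q])
    return int(out[0]) if np.asarray(query).ndim == 1 else out


def dt_proba(model: TreeModel, query: np.ndarray) -> np.ndarray:
    """Leaf class proportions, shape (n_queries, n_classes)."""
    q = np.atleast_2d(np.asarray(query, dtype=float))
    out = np.array([_tree_leaf(model, row)["proportions"] for row in q])
    return out[0] if np.asarray(query).ndim == 1 else out


# ---------------------------------------------------------------- serialization


def _model_payload(model: KNNModel | SVMModel | TreeModel) -> dict[str, Any]:
    if isinstance(model, KNNModel):
        return {
            "algorithm": "knn",
            "k": model.k,
            "classes": model.classes.tolist(),
            "X": model.X.tolist(),
            "y": model.y.tolist(),
            "scaler": {"mean": model.scaler.mean.tolist(), "sd": model.scaler.sd.tolist()},
        }
    if isinstance(model, SVMModel):
        return {
            "algorithm": "svm",
            "C": model.C,
            "kernel": {"gamma": model.kernel.gamma, "r": model.kernel.r, "degree": model.kernel.degree},
            "classes": model.classes.tolist(),
            "n_features": model.n_features,
            "scaler": {"mean": model.scaler.mean.tolist(), "sd": model.scaler.sd.tolist()},
            "machines": [
                {
                    "dual_coef": m.dual_coef.tolist(),
                    "support_vectors": m.support_vectors.tolist(),
                    "bias": m.bias,
                    "converged": m.converged,
                }
                for m in model.machines
            ],
        }
    if isinstance(model, TreeModel):
        return {
            "algorithm": "dt",
            "max_nodes": model.max_nodes,
            "n_classes": model.n_classes,
            "nodes": model.nodes,
        }
    raise TypeError(f"unknown model type {type(model)!r}")


def save_model(model: KNNModel | SVMModel | TreeModel, path: str | os.PathLike) -> None:
    payload = {"format_version": MODEL_FORMAT_VERSION, **_model_payload(model)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path: str | os.PathLike) -> KNNModel | SVMModel | TreeModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')!r}")
    algo = payload["algorithm"]
    if algo == "knn":
        scaler = _Scaler(np.array(payload["scaler"]["mean"]), np.array(payload["scaler"]["sd"]))
        return KNNModel(
            np.array(payload["X"]),
            np.array(payload["y"], dtype=int),
            int(payload["k"]),
            np.array(payload["classes"], dtype=int),
            scaler,
        )
    if algo == "svm":
        kernel = KernelParams(**payload["kernel"])
        scaler = _Scaler(np.array(payload["scaler"]["mean"]), np.array(payload["scaler"]["sd"]))
        machines = [
            _BinarySVM(
                np.array(m["dual_coef"]),
                np.array(m["support_vectors"]).reshape(-1, payload["n_features"]),
                float(m["bias"]),
                bool(m["converged"]),
            )
            for m in payload["machines"]
        ]
        return SVMModel(
            np.array(payload["classes"], dtype=int),
            machines,
            float(payload["C"]),
            kernel,
            scaler,
            int(payload["n_features"]),
        )
    if algo == "dt":
        return TreeModel(payload["nodes"], int(payload["n_classes"]), int(payload["max_nodes"]))
    raise ValueError(f"unknown algorithm {algo!r}")
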