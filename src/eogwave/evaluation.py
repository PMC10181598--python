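"""Splitting, confusion counts, derived metrics, ROC curves and Jaccard index.

The evaluation layer reproduces the study's reporting structure: a single
stratified train/test split (80/20, seeded), per-class one-vs-rest confusion
counts with sensitivity / specificity / accuracy / precision percentages,
micro-averaged one-vs-rest ROC curves, and the Jaccard (intersection-over-
union) similarity between predicted and true label sequences.

For single-label multiclass predictions the micro Jaccard index equals
``a / (2 - a)`` where ``a`` is exact-match accuracy — useful both as an
invariant and as the closed form for chance agreement (a = 1/C for C
balanced classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .classifiers import (
    KernelParams,
    dt_fit,
    dt_predict,
    dt_proba,
    knn_fit,
    knn_predict,
    knn_scores,
    svm_decision,
    svm_fit,
    svm_predict,
)
from .features import FeatureMatrix

__all__ = [
    "SplitSpec",
    "ConfusionCounts",
    "MetricRow",
    "ROCCurve",
    "ModelConfigs",
    "split_indices",
    "train_test_split",
    "confusion_matrix",
    "binary_counts",
    "derived_metrics",
    "roc_curve",
    "jaccard_index",
    "evaluate_all",
]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test partition parameters."""

    train_fraction: float = 0.8
    seed: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split.

    The global train size is ``round(n * fraction)``; it is apportioned to
    classes by largest-remainder rounding so each class's train share is
    within one row of its target.  Deterministic per seed.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        thin = classes[counts < 2].tolist()
        raise ValueError(f"classes {thin} have fewer than 2 rows; cannot split")
    target = int(round(labels.size * spec.train_fraction))
    exact = counts * spec.train_fraction
    take = np.floor(exact).astype(int)
    # keep every class represented on both sides
    take = np.clip(take, 1, counts - 1)
    remainder = exact - np.floor(exact)
    order = np.argsort(-remainder, kind="stable")  # ties: lower class id first
    for c in order:
        if take.sum() >= target:
            break
        if take[c] < counts[c] - 1:
            take[c] += 1
    rng = np.random.default_rng(spec.seed)
    train, test = [], []
    for c, cls in enumerate(classes):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        train.append(idx[: take[c]])
        test.append(idx[take[c] :])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def train_test_split(
    matrix: FeatureMatrix, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified random partition of a feature matrix."""
    train_idx, test_idx = split_indices(matrix.window_labels, spec)
    return matrix.subset(train_idx), matrix.subset(test_idx)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None
) -> np.ndarray:
    """Count grid with ``grid[t, p]`` = samples of true class t predicted p."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label sequences must align")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    if np.any((y_true < 0) | (y_true >= n_classes) | (y_pred < 0) | (y_pred >= n_classes)):
        raise ValueError(f"labels out of range 0..{n_classes - 1}")
    grid = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(grid, (y_true, y_pred), 1)
    return grid


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN; real-valued counts are accepted so published
    averaged rows can be re-derived as worked examples."""

    TP: float
    TN: float
    FP: float
    FN: float

    def __post_init__(self) -> None:
        values = (self.TP, self.TN, self.FP, self.FN)
        if any(v < 0 for v in values):
            raise ValueError("confusion counts must be non-negative")
        if all(v == 0 for v in values):
            raise ValueError("at least one confusion count must be positive")


def binary_counts(grid: np.ndarray, class_id: int) -> ConfusionCounts:
    """Reduce a multiclass count grid to one class's one-vs-rest counts."""
    grid = np.asarray(grid)
    if not 0 <= class_id < grid.shape[0]:
        raise ValueError(f"class {class_id} out of range for a {grid.shape[0]}-class grid")
    tp = float(grid[class_id, class_id])
    fn = float(grid[class_id].sum()) - tp
    fp = float(grid[:, class_id].sum()) - tp
    tn = float(grid.sum()) - tp - fn - fp
    return ConfusionCounts(tp, tn, fp, fn)


@dataclass(frozen=True)
class MetricRow:
    """Derived percentages; a metric with a zero denominator is None."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
        }


def _ratio(num: float, den: float) -> float | None:
    return 100.0 * num / den if den > 0 else None


def derived_metrics(counts: ConfusionCounts) -> MetricRow:
    """Sensitivity, specificity, accuracy and precision (percent)."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    return MetricRow(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        precision=_ratio(tp, tp + fp),
    )


@dataclass
class ROCCurve:
    """One-vs-rest micro-averaged ROC curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    sensitivity_at_half: float
    specificity_at_half: float

    def as_dict(self) -> dict[str, Any]:
        return {
            "auc": self.auc,
            "sensitivity_at_half": self.sensitivity_at_half,
            "specificity_at_half": self.specificity_at_half,
        }


def _binary_roc(scores: np.ndarray, truth: np.ndarray) -> ROCCurve:
    pos = truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    # group tied scores: cumulative counts at the last element of each tie block
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    block_ends = np.append(distinct, s.size - 1)
    cum_tp = np.cumsum(p)[block_ends]
    cum_fp = np.cumsum(~p)[block_ends]
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    thresholds = np.concatenate([[np.inf], s[block_ends]])
    auc = float(np.trapezoid(tpr, fpr))
    predicted_pos = scores >= 0.5
    sens = 100.0 * float(np.sum(predicted_pos & pos)) / n_pos
    spec = 100.0 * float(np.sum(~predicted_pos & ~pos)) / n_neg
    return ROCCurve(fpr, tpr, thresholds, auc, sens, spec)


def roc_curve(scores: np.ndarray, y_true: np.ndarray, n_classes: int | None = None) -> ROCCurve:
    """ROC curve from scores.

    1-D scores with binary (0/1) truth give the plain binary curve.  A 2-D
    ``(n, n_classes)`` score array with multiclass truth is reduced by
    micro-averaging: all one-vs-rest (score, indicator) pairs are pooled
    into one binary problem.  The operating point at cutoff 0.5 is reported
    alongside the trapezoidal AUC.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if scores.ndim == 1:
        if scores.shape != y_true.shape:
            raise ValueError("scores and labels must align")
        if not set(np.unique(y_true)) <= {0, 1}:
            raise ValueError("1-D scores require binary 0/1 truth")
        return _binary_roc(scores, y_true)
    if scores.ndim != 2 or scores.shape[0] != y_true.size:
        raise ValueError("scores must be (n_samples, n_classes) aligned with labels")
    if n_classes is None:
        n_classes = scores.shape[1]
    onehot = np.zeros((y_true.size, n_classes), dtype=int)
    onehot[np.arange(y_true.size), y_true] = 1
    return _binary_roc(scores.ravel(), onehot.ravel())


def jaccard_index(y_true: np.ndarray, y_pred: np.ndarray, mode: str = "micro") -> float:
    """Intersection-over-union similarity of two label sequences.

    micro: pooled ``sum TP / sum (TP + FP + FN)`` over classes;
    macro: unweighted mean of per-class IoU over classes present in either
    sequence.  Both lie in [0, 1]; identical sequences give 1.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    classes = np.union1d(y_true, y_pred)
    tp = np.array([np.sum((y_true == c) & (y_pred == c)) for c in classes], dtype=float)
    fp = np.array([np.sum((y_true != c) & (y_pred == c)) for c in classes], dtype=float)
    fn = np.array([np.sum((y_true == c) & (y_pred != c)) for c in classes], dtype=float)
    if mode == "micro":
        union = tp.sum() + fp.sum() + fn.sum()
        return float(tp.sum() / union) if union else 1.0
    if mode == "macro":
        union = tp + fp + fn
        return float(np.mean(np.divide(tp, union, out=np.ones_like(tp), where=union > 0)))
    raise ValueError(f"unknown mode {mode!r}; expected 'micro' or 'macro'")


@dataclass(frozen=True)
class ModelConfigs:
    """Hyperparameters of the three classifiers trained by evaluate_all."""

    k: int = 4
    C: float = 14.5
    kernel: KernelParams | None = None
    max_nodes: int = 10
    svm_seed: int = 4
    jaccard_mode: str = "micro"


@dataclass
class AlgorithmResult:
    train_jaccard: float
    test_jaccard: float
    test_accuracy: float
    confusion: np.ndarray
    per_class: dict[int, MetricRow]
    roc: ROCCurve

    def as_dict(self) -> dict[str, Any]:
        return {
            "train_jaccard": self.train_jaccard,
            "test_jaccard": self.test_jaccard,
            "test_accuracy": self.test_accuracy,
            "confusion": self.confusion.tolist(),
            "per_class": {str(c): row.as_dict() for c, row in self.per_class.items()},
            "roc": self.roc.as_dict(),
        }


@dataclass
class EvaluationReport:
    split: SplitSpec
    configs: ModelConfigs
    n_train: int
    n_test: int
    algorithms: dict[str, AlgorithmResult] = field(default_factory=dict)
    models: dict[str, Any] = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict[str, Any]:
        return {
            "split": {"train_fraction": self.split.train_fraction, "seed": self.split.seed},
            "n_train": self.n_train,
            "n_test": self.n_test,
            "jaccard_mode": self.configs.jaccard_mode,
            "algorithms": {name: res.as_dict() for name, res in self.algorithms.items()},
        }


def evaluate_all(
    matrix: FeatureMatrix,
    split: SplitSpec = SplitSpec(),
    configs: ModelConfigs = ModelConfigs(),
) -> EvaluationReport:
    """Train KNN, SVM and the Gini tree on one stratified split and report
    train/test Jaccard, confusion grids, per-class metrics and ROC summaries.

    Deterministic for a given matrix, split seed and SVM seed.
    """
    train, test = train_test_split(matrix, split)
    n_classes = int(matrix.window_labels.max()) + 1
    report = EvaluationReport(split, configs, train.n_windows, test.n_windows)

    knn = knn_fit(train.X, train.window_labels, k=configs.k)
    svm = svm_fit(
        train.X,
        train.window_labels,
        C=configs.C,
        params=configs.kernel,
        seed=configs.svm_seed,
    )
    tree = dt_fit(train.X, train.window_labels, max_nodes=configs.max_nodes)
    report.models = {"knn": knn, "svm": svm, "dt": tree}

    def svm_scores01(X: np.ndarray) -> np.ndarray:
        # squash decision values to (0, 1) so the 0.5 cutoff is meaningful
        return 1.0 / (1.0 + np.exp(-np.atleast_2d(svm_decision(svm, X))))

    fitted = {
        "knn": (lambda X: knn_predict(knn, X), lambda X: np.atleast_2d(knn_scores(knn, X))),
        "svm": (lambda X: svm_predict(svm, X), svm_scores01),
        "dt": (lambda X: dt_predict(tree, X), lambda X: np.atleast_2d(dt_proba(tree, X))),
    }
    for name, (predict, scores) in fitted.items():
        pred_train = np.asarray(predict(train.X))
        pred_test = np.asarray(predict(test.X))
        grid = confusion_matrix(test.window_labels, pred_test, n_classes)
        per_class = {
            c: derived_metrics(binary_counts(grid, c))
            for c in range(n_classes)
            if grid[c].sum() or grid[:, c].sum()
        }
        report.algorithms[name] = AlgorithmResult(
            train_jaccard=jaccard_index(
                train.window_labels, pred_train, configs.jaccard_mode
            ),
            test_jaccard=jaccard_index(
                test.window_labels, pred_test, configs.jaccard_mode
            ),
            test_accuracy=float(np.mean(pred_test == test.window_labels)),
            confusion=grid,
            per_class=per_class,
            roc=roc_curve(scores(test.X), test.window_labels, n_classes),
        )
    return report
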