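"""1-nearest-neighbour classification and per-class evaluation.

The classifier is deliberately simple: with k = 1 every query takes the
label of its single nearest training sample under Euclidean distance, so
fine distinctions between audiogram shapes survive (no vote smoothing).
Evaluation is 5-fold cross-validation with stratified folds; the confusion
matrix is accumulated over folds and summarized one-vs-rest per class:
precision, recall, specificity, F-score (β = 1) and per-class accuracy,
which for a multi-class confusion matrix equals per-class recall.
The overall row holds unweighted macro averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from audioshape.features import (
    FeatureVector,
    final_arrangement,
    fit_nested,
    fit_residual_map,
)

__all__ = [
    "EvalReport",
    "knn_fit_predict",
    "metrics_from_confusion",
    "stratified_folds",
    "cross_validate",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f_score")


@dataclass
class EvalReport:
    """Per-class and macro-averaged classification metrics."""

    classes: tuple
    per_class: Dict[int, Dict[str, float]]
    overall: Dict[str, float]
    confusion: np.ndarray
    warnings: List[str] = field(default_factory=list)
    per_dataset: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "classes": list(self.classes),
            "per_class": {str(c): m for c, m in self.per_class.items()},
            "overall": self.overall,
            "confusion": self.confusion.tolist(),
            "warnings": self.warnings,
        }
        if self.per_dataset is not None:
            d["per_dataset"] = self.per_dataset
        return d


def _as_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    registry = vectors[0].names
    for fv in vectors[1:]:
        if fv.names != registry:
            raise ValueError(
                f"feature registry mismatch: {fv.id!r} has different feature names"
            )
    return np.vstack([fv.values for fv in vectors])


def knn_fit_predict(
    train: Sequence[FeatureVector],
    test: Sequence[FeatureVector],
    k: int = 1,
) -> np.ndarray:
    """Label each test vector by its nearest training vectors.

    k = 1 (the default) assigns the label of the single closest training
    sample; larger k takes the majority vote, ties broken toward the
    neighbour set's closest member.  Exact distance ties are broken by the
    lowest training index.
    """
    if not len(train):
        raise ValueError("empty training set")
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.array([fv.label for fv in train])
    if any(l is None for l in labels):
        raise ValueError("all training vectors must be labelled")
    x_train = _as_matrix(list(train) + list(test))[: len(train)]
    x_test = _as_matrix(list(train) + list(test))[len(train):]
    if not len(test):
        return np.array([], dtype=int)
    d = cdist(x_test, x_train)
    if k == 1:
        return labels[np.argmin(d, axis=1)]
    out = np.empty(len(test), dtype=int)
    nn = np.argsort(d, kind="stable", axis=1)[:, :k]
    for i, neigh in enumerate(nn):
        votes = labels[neigh]
        vals, counts = np.unique(votes, return_counts=True)
        winners = vals[counts == counts.max()]
        # among tied vote counts, prefer the label of the closest neighbour
        out[i] = next(v for v in votes if v in winners)
    return out


def metrics_from_confusion(cm: np.ndarray, classes: Optional[Sequence[int]] = None) -> EvalReport:
    """One-vs-rest metrics per class from a k×k confusion matrix.

    Rows are true classes, columns predictions.  A zero denominator yields a
    metric of 0 and a warning flag in the report.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.number):
        raise ValueError("confusion matrix must hold nonnegative counts")
    n_classes = cm.shape[0]
    classes = tuple(classes) if classes is not None else tuple(range(1, n_classes + 1))
    if len(classes) != n_classes:
        raise ValueError("class list does not match matrix size")
    total = cm.sum()
    per_class = {}
    warn = []

    def safe(num, den, name, cls):
        if den == 0:
            warn.append(f"class {cls}: {name} undefined (zero denominator), reported as 0")
            return 0.0
        return float(num / den)

    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision = safe(tp, tp + fp, "precision", c)
        recall = safe(tp, tp + fn, "recall", c)
        specificity = safe(tn, tn + fp, "specificity", c)
        f_score = safe(2 * precision * recall, precision + recall, "f_score", c)
        per_class[c] = {
            "accuracy": recall,  # per-class accuracy == per-class recall
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f_score": f_score,
        }
    overall = {
        m: float(np.mean([per_class[c][m] for c in classes])) for m in METRIC_NAMES
    }
    return EvalReport(classes=classes, per_class=per_class, overall=overall,
                      confusion=cm, warnings=warn)


def stratified_folds(
    labels: Sequence[int],
    n_folds: int,
    seed: int = 0,
) -> np.ndarray:
    """Seeded stratified fold assignment (0..n_folds−1 per sample).

    Members of each class are shuffled and dealt round-robin over the folds,
    so a class with fewer members than folds is spread one per fold — its
    members are effectively evaluated leave-one-out (a warning is issued).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.size, dtype=int)
    start = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < n_folds:
            warnings.warn(
                f"class {c} has {idx.size} < {n_folds} members; "
                "falling back to leave-one-out for its members",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        folds[idx] = (np.arange(idx.size) + start) % n_folds
        start += idx.size  # stagger classes so fold sizes stay balanced
    return folds


def cross_validate(
    data: Sequence[FeatureVector],
    n_folds: int = 5,
    seed: int = 0,
    knn_k: int = 1,
    build_final: bool = True,
    whole_set_fitting: bool = False,
) -> EvalReport:
    """Stratified k-fold cross-validation of the 1-NN classifier.

    ``data`` holds labelled reduced feature vectors.  When ``build_final``
    is set, the nested-feature model and residual map are fitted inside each
    training fold (fold-safe, the default) — or once on the whole set when
    ``whole_set_fitting`` is set — and the 31-feature final arrangement is used
    for classification.  The confusion matrix is accumulated over folds.
    """
    data = list(data)
    labels = [fv.label for fv in data]
    if any(l is None for l in labels):
        raise ValueError("cross-validation requires labelled feature vectors")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("cross-validation requires at least 2 classes")
    folds = stratified_folds(labels, n_folds, seed=seed)
    class_index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)

    leak_model = leak_rmap = None
    if build_final and whole_set_fitting:
        leak_model = fit_nested(data, k=None)
        leak_rmap = fit_residual_map(data)

    for fold in range(n_folds):
        train = [fv for fv, f in zip(data, folds) if f != fold]
        test = [fv for fv, f in zip(data, folds) if f == fold]
        if not test:
            continue
        if build_final:
            if whole_set_fitting:
                model, rmap = leak_model, leak_rmap
            else:
                model = fit_nested(train, k=None)
                rmap = fit_residual_map(train)
            train = [final_arrangement(fv, model, rmap) for fv in train]
            test = [final_arrangement(fv, model, rmap) for fv in test]
        predicted = knn_fit_predict(train, test, k=knn_k)
        for fv, pred in zip(test, predicted):
            cm[class_index[fv.label], class_index[pred]] += 1

    return metrics_from_confusion(cm, classes=classes)
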