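"""Nearest-centroid classification and the evaluation metrics.

Prediction operates on learned representations: by default the pooled
(concatenated) network outputs of all views; single-view and
discriminant-score (``H Gamma``) modes are available.  A sample is
assigned to the class whose mean representation is closest in Euclidean
distance, with ties broken toward the class earlier in sorted label
order.  Negative distances serve as decision values for AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "CentroidModel",
    "MetricsReport",
    "ncc_fit",
    "ncc_predict",
    "classification_metrics",
    "ncc_evaluate",
]


@dataclass
class CentroidModel:
    classes: np.ndarray
    centroids: np.ndarray  # K x q
    representation: str = "pooled-H"


@dataclass
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    auroc: float | None
    precision: float
    recall: float
    f1: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def ncc_fit(scores: np.ndarray, labels, representation: str = "pooled-H") -> CentroidModel:
    """Per-class mean of rows; classes stored in sorted label order."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes, inverse, counts = np.unique(labels, return_inverse=True,
                                         return_counts=True)
    if (counts == 0).any() or len(classes) < 1:
        raise ValueError("empty class")
    centroids = np.stack([scores[inverse == k].mean(axis=0)
                          for k in range(len(classes))])
    return CentroidModel(classes, centroids, representation)


def ncc_predict(model: CentroidModel, scores: np.ndarray):
    """Nearest centroid by Euclidean distance.

    Returns ``(labels, decision_values)`` where decision values are the
    negative distances to each class centroid (columns in class order).
    Ties go to the class earlier in sorted label order (argmin takes the
    first minimum).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[None, :]
    if scores.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"scores have dimension {scores.shape[1]}, centroids "
            f"{model.centroids.shape[1]}"
        )
    d2 = (
        (scores * scores).sum(axis=1, keepdims=True)
        - 2.0 * scores @ model.centroids.T
        + (model.centroids * model.centroids).sum(axis=1)
    )
    d2 = np.maximum(d2, 0.0)
    dist = np.sqrt(d2)
    return model.classes[np.argmin(dist, axis=1)], -dist


def classification_metrics(y_true, y_pred, decision_values=None) -> MetricsReport:
    """Accuracy, balanced accuracy, AUROC and (weighted) precision/recall/F1.

    AUROC is computed from decision values: binary problems use the
    positive-class column, multiclass uses macro one-vs-rest; it is
    omitted (None) when decision values are absent.  Binary
    precision/recall/F1 treat the larger label as positive; for K > 2
    the unweighted fields hold macro averages.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    classes = np.unique(y_true)
    if not np.isin(np.unique(y_pred), classes).all():
        raise ValueError("y_pred contains a label unseen in y_true")
    binary = len(classes) == 2
    avg = "binary" if binary else "macro"
    pos_label = classes[-1] if binary else 1
    accuracy = _skm.accuracy_score(y_true, y_pred)
    balanced = _skm.balanced_accuracy_score(y_true, y_pred)
    auroc = None
    if decision_values is not None:
        dv = np.asarray(decision_values, dtype=float)
        if binary:
            score = dv[:, 1] if dv.ndim == 2 else dv
            auroc = _skm.roc_auc_score(y_true == pos_label, score)
        else:
            # softmax the negative distances into pseudo-probabilities
            e = np.exp(dv - dv.max(axis=1, keepdims=True))
            prob = e / e.sum(axis=1, keepdims=True)
            auroc = _skm.roc_auc_score(y_true, prob, multi_class="ovr",
                                       average="macro", labels=classes)
    kw = dict(zero_division=0)
    precision = _skm.precision_score(y_true, y_pred, average=avg,
                                     pos_label=pos_label, **kw)
    recall = _skm.recall_score(y_true, y_pred, average=avg,
                               pos_label=pos_label, **kw)
    f1 = _skm.f1_score(y_true, y_pred, average=avg, pos_label=pos_label, **kw)
    return MetricsReport(
        accuracy=float(accuracy),
        balanced_accuracy=float(balanced),
        auroc=None if auroc is None else float(auroc),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        precision_weighted=float(_skm.precision_score(
            y_true, y_pred, average="weighted", **kw)),
        recall_weighted=float(_skm.recall_score(
            y_true, y_pred, average="weighted", **kw)),
        f1_weighted=float(_skm.f1_score(
            y_true, y_pred, average="weighted", **kw)),
    )


def ncc_evaluate(train_scores, train_labels, test_scores, test_labels) -> MetricsReport:
    """Fit NCC on training scores, report metrics on the test scores."""
    model = ncc_fit(train_scores, train_labels)
    pred, dv = ncc_predict(model, test_scores)
    return classification_metrics(test_labels, pred, dv)
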