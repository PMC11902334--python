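"""Confusion matrices, accuracies, one-vs-rest ROC/AUC and diagnostic plots.

Conventions: confusion-matrix rows are true classes, columns predicted
classes, both ordered by ``class_order``.  ROC curves sweep the positive
class's score with the trapezoidal AUC (tied score pairs receive half
credit — the Mann-Whitney convention).  Plot operations always return the
numeric point set they draw, so every figure is testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import InputError
from .twolayer import Layer1Model, composition_features

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "roc_auc_one_vs_rest",
    "composition_scatter",
]


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of items with true class i predicted as j."""

    counts: np.ndarray
    class_order: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or \
                self.counts.shape[0] != self.counts.shape[1]:
            raise InputError("confusion counts must be square")
        if self.counts.shape[0] != len(self.class_order):
            raise InputError("counts size must match class_order")
        if np.any(self.counts < 0):
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.class_order)
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def confusion(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    """Tally a confusion matrix aligned to ``class_order``."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    class_order = np.asarray(class_order)
    if true_labels.shape[0] != predicted_labels.shape[0]:
        raise InputError("true and predicted label lists differ in length")
    known = set(class_order.tolist())
    for name, labs in (("true", true_labels), ("predicted", predicted_labels)):
        unknown = set(labs.tolist()) - known
        if unknown:
            raise InputError(f"{name} labels {sorted(map(str, unknown))} are "
                             "not in class_order")
    counts = _skm.confusion_matrix(true_labels, predicted_labels,
                                   labels=class_order)
    return ConfusionMatrix(counts=counts, class_order=class_order)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of items on the confusion-matrix diagonal."""
    if cm.total == 0:
        raise InputError("cannot compute accuracy of an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def roc_auc_one_vs_rest(scores, true_labels, positive_class, class_order):
    """One-vs-rest ROC curve and AUC for one class.

    ``scores`` is the (n, C) per-class score matrix with columns aligned
    to ``class_order``; the positive score of each item is its score for
    ``positive_class``.  Returns ``(points, auc)`` where ``points`` is an
    (m, 2) array of (false-positive rate, true-positive rate) pairs from
    (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    true_labels = np.asarray(true_labels)
    class_order = np.asarray(class_order)
    if scores.ndim != 2 or scores.shape[1] != len(class_order):
        raise InputError("scores must be (n, len(class_order))")
    if scores.shape[0] != true_labels.shape[0]:
        raise InputError("scores and true_labels differ in length")
    pos = np.flatnonzero(class_order == positive_class)
    if pos.size != 1:
        raise InputError(f"positive class {positive_class!r} not in class_order")
    y = (true_labels == class_order[pos[0]]).astype(int)
    if y.min() == y.max():
        raise InputError("ROC needs both positive and negative items")
    s = scores[:, pos[0]]
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc


def composition_scatter(mocks, layer1: Layer1Model, x_class, y_class,
                        ax=None, path=None) -> pd.DataFrame:
    """Scatter of mock compositions for two classes, one point per mock.

    Each mock contributes (percentage assigned to ``x_class``, percentage
    assigned to ``y_class``), colour-coded by its true sample label.  The
    numeric point set is returned as a DataFrame; drawing happens on
    ``ax`` (created on demand) and the figure is saved to ``path`` if
    given.
    """
    class_order = list(layer1.class_order)
    for cls in (x_class, y_class):
        if cls not in class_order:
            raise InputError(f"class {cls!r} not in the model's class order")
    xi, yi = class_order.index(x_class), class_order.index(y_class)
    rows = []
    for mock in mocks:
        comp = composition_features(mock, layer1)
        rows.append({"mock_id": mock.mock_id, "true_label": mock.sample_label,
                     "x_pct": comp[xi], "y_pct": comp[yi]})
    points = pd.DataFrame(rows)
    if ax is None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        _, ax = plt.subplots(figsize=(5, 4))
    for label, grp in points.groupby("true_label", sort=True):
        ax.scatter(grp["x_pct"], grp["y_pct"], s=12, alpha=0.7,
                   label=str(label))
    ax.set_xlabel(f"beads classified as {x_class} (%)")
    ax.set_ylabel(f"beads classified as {y_class} (%)")
    ax.legend(title="true label", fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return points
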