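"""The two-layer bead -> sample classification framework.

Layer 1 classifies *individual beads* from their 8-frequency peak-amplitude
vectors — either a coarse k-nearest-neighbour model (k = 100, Euclidean
distance on z-scored features) or a linear discriminant (Gaussian classes
with a shared pooled within-class covariance and empirical priors).
Individual beads are only weakly informative: under the assay's chemistry
a bead either captured analyte or did not, so per-bead accuracy is low.

Layer 2 therefore never sees beads.  Each *mock experiment* (a disjoint
group of beads treated as one sample) is reduced to its **composition
vector** — the percentage of its beads that layer 1 assigned to each
class — and a second coarse kNN is fitted on the composition vectors of
the training mocks against their true sample labels.  Aggregating a few
dozen weak per-bead votes into a composition estimate is what rescues the
sample-level accuracy.

Tie-breaking is fully deterministic: among classes with the maximal
neighbour count (or posterior) the class with the smaller summed neighbour
distance wins, then the earlier class in ``class_order``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import SplitSpec
from .errors import InputError
from .resample import MockExperiment, make_training_mocks, LABEL_COLUMN_DEFAULT
from .tables import amplitude_matrix

__all__ = [
    "KNN_COARSE_K",
    "Layer1Model",
    "TwoLayerModel",
    "fit_knn",
    "predict_knn",
    "fit_discriminant",
    "predict_discriminant",
    "composition_features",
    "fit_two_layer",
    "predict_sample",
    "save_model",
    "load_model",
]

#: Neighbour count of the "coarse" kNN preset.
KNN_COARSE_K = 100


@dataclass
class Layer1Model:
    """A fitted bead-level (or composition-level) classifier.

    ``kind`` is ``"coarse_knn"`` (stores the z-scored training set) or
    ``"linear_discriminant"`` (stores class means, the inverse pooled
    covariance and priors).  ``class_order`` fixes the column order of all
    score matrices and the final tie-break.
    """

    kind: str
    class_order: np.ndarray
    # kNN state
    k: int | None = None
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    train_z: np.ndarray | None = None
    train_labels_idx: np.ndarray | None = None
    # discriminant state
    class_means: np.ndarray | None = None
    pooled_cov: np.ndarray | None = None
    pooled_cov_inv: np.ndarray | None = None
    priors: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        if self.kind == "coarse_knn":
            return self.train_z.shape[1]
        return self.class_means.shape[1]


def _as_matrix(features) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise InputError("features must be a 2-D (n, d) matrix")
    return x


def fit_knn(features, labels, k: int = KNN_COARSE_K) -> Layer1Model:
    """Fit a coarse kNN model: z-score the features and store them.

    The effective neighbour count at prediction time is ``min(k, n)``.
    Zero-variance features get unit scale so they carry no weight without
    raising an error.
    """
    x = _as_matrix(features)
    labels = np.asarray(labels)
    if x.shape[0] < 1:
        raise InputError("kNN requires at least one training point")
    if labels.shape[0] != x.shape[0]:
        raise InputError("labels length must match the feature rows")
    if k < 1:
        raise InputError("k must be >= 1")
    class_order, y_idx = np.unique(labels, return_inverse=True)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return Layer1Model(
        kind="coarse_knn", class_order=class_order, k=int(k),
        feature_mean=mean, feature_scale=scale,
        train_z=(x - mean) / scale, train_labels_idx=y_idx.astype(int))


def _break_ties(counts: np.ndarray, sum_dist: np.ndarray) -> np.ndarray:
    """argmax over classes: max count, then min summed distance, then order."""
    n, c = counts.shape
    best = np.zeros(n, dtype=int)
    top = counts.max(axis=1, keepdims=True)
    is_top = counts == top
    for i in range(n):
        cand = np.flatnonzero(is_top[i])
        if cand.size > 1:
            d = sum_dist[i, cand]
            cand = cand[d == d.min()]
        best[i] = cand[0]  # earliest in class_order
    return best


def predict_knn(model: Layer1Model, features, chunk: int = 2048):
    """Predict labels and per-class neighbour-fraction scores.

    Scores are the fractions of each class among the k nearest training
    points (Euclidean distance on z-scored features); rows sum to 1.
    """
    if model.kind != "coarse_knn":
        raise InputError("predict_knn requires a coarse_knn model")
    x = _as_matrix(features)
    if x.shape[1] != model.n_features:
        raise InputError(
            f"feature dimension {x.shape[1]} does not match the model's "
            f"{model.n_features}")
    z = (x - model.feature_mean) / model.feature_scale
    n_train = model.train_z.shape[0]
    k = min(model.k, n_train)
    n_classes = len(model.class_order)
    labels_idx = np.empty(x.shape[0], dtype=int)
    scores = np.empty((x.shape[0], n_classes))
    for lo in range(0, x.shape[0], chunk):
        zc = z[lo:lo + chunk]
        d = cdist(zc, model.train_z)
        nn = np.argpartition(d, k - 1, axis=1)[:, :k]
        nn_labels = model.train_labels_idx[nn]
        nn_dist = np.take_along_axis(d, nn, axis=1)
        counts = np.zeros((zc.shape[0], n_classes))
        sum_dist = np.zeros((zc.shape[0], n_classes))
        rows = np.repeat(np.arange(zc.shape[0]), k)
        np.add.at(counts, (rows, nn_labels.ravel()), 1.0)
        np.add.at(sum_dist, (rows, nn_labels.ravel()), nn_dist.ravel())
        sum_dist[counts == 0] = np.inf
        labels_idx[lo:lo + chunk] = _break_ties(counts, sum_dist)
        scores[lo:lo + chunk] = counts / k
    return model.class_order[labels_idx], scores


def fit_discriminant(features, labels) -> Layer1Model:
    """Fit a linear discriminant: Gaussian classes, shared pooled covariance.

    Priors are empirical class frequencies.  If the pooled covariance is
    singular (or numerically close), a ridge of 1e-6 times the mean
    diagonal is added.
    """
    x = _as_matrix(features)
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise InputError("labels length must match the feature rows")
    class_order, y_idx = np.unique(labels, return_inverse=True)
    n, d = x.shape
    c = len(class_order)
    if c < 2:
        raise InputError("linear discriminant requires at least two classes")
    counts = np.bincount(y_idx, minlength=c)
    if counts.min() < 2:
        lab = class_order[counts.argmin()]
        raise InputError(f"class {lab!r} has fewer than 2 rows")
    if n <= d:
        warnings.warn("fewer samples than features + 1; the pooled covariance "
                      "estimate will be unstable", stacklevel=2)
    means = np.stack([x[y_idx == i].mean(axis=0) for i in range(c)])
    resid = x - means[y_idx]
    cov = resid.T @ resid / (n - c)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0 or eigvals.max() / max(eigvals.min(), 1e-300) > 1e12:
        cov = cov + 1e-6 * np.mean(np.diag(cov)) * np.eye(d)
    return Layer1Model(
        kind="linear_discriminant", class_order=class_order,
        class_means=means, pooled_cov=cov,
        pooled_cov_inv=np.linalg.inv(cov), priors=counts / n)


def predict_discriminant(model: Layer1Model, features):
    """Predict labels and class posteriors (rows sum to 1)."""
    if model.kind != "linear_discriminant":
        raise InputError("predict_discriminant requires a linear_discriminant "
                         "model")
    x = _as_matrix(features)
    if x.shape[1] != model.n_features:
        raise InputError(
            f"feature dimension {x.shape[1]} does not match the model's "
            f"{model.n_features}")
    w = model.pooled_cov_inv @ model.class_means.T            # (d, C)
    # linear discriminant scores; the shared quadratic term cancels in the
    # softmax, so these yield the exact Gaussian posteriors
    const = -0.5 * np.einsum("cd,dc->c", model.class_means, w) \
        + np.log(model.priors)
    g = x @ w + const                                          # (n, C)
    g -= g.max(axis=1, keepdims=True)
    post = np.exp(g)
    post /= post.sum(axis=1, keepdims=True)
    # ties (measure-zero) fall to the earlier class in class_order
    labels_idx = post.argmax(axis=1)
    return model.class_order[labels_idx], post


def _predict_layer1(model: Layer1Model, features):
    if model.kind == "coarse_knn":
        return predict_knn(model, features)
    return predict_discriminant(model, features)


def composition_features(mock: MockExperiment, layer1: Layer1Model) -> np.ndarray:
    """Percentage of the mock's beads assigned to each class by layer 1.

    Returns a vector aligned to ``layer1.class_order`` summing to 100.
    """
    if len(mock) == 0:
        raise InputError("cannot compute a composition for an empty mock")
    labels, _ = _predict_layer1(layer1, amplitude_matrix(mock.peaks))
    order = {lab: i for i, lab in enumerate(layer1.class_order)}
    counts = np.zeros(len(layer1.class_order))
    for lab in labels:
        counts[order[lab]] += 1
    return 100.0 * counts / len(mock)


@dataclass
class TwoLayerModel:
    """Fitted two-layer model plus everything needed to reproduce it."""

    layer1: Layer1Model
    layer2: Layer1Model
    class_order: np.ndarray
    spec: SplitSpec
    layer1_kind: str
    label_col: str = LABEL_COLUMN_DEFAULT


def fit_two_layer(layer1_train: pd.DataFrame, layer2_train: pd.DataFrame,
                  spec: SplitSpec, layer1_kind: str = "coarse_knn",
                  label_col: str = LABEL_COLUMN_DEFAULT) -> TwoLayerModel:
    """Fit layer 1 on beads, then layer 2 on training-mock compositions."""
    if len(layer1_train) == 0 or len(layer2_train) == 0:
        raise InputError("both layer-1 and layer-2 training tables must be "
                         "non-empty")
    l1_classes = np.unique(layer1_train[label_col].to_numpy())
    l2_classes = np.unique(layer2_train[label_col].to_numpy())
    if not np.array_equal(l1_classes, l2_classes):
        raise InputError("layer-1 and layer-2 training tables must cover the "
                         "same classes")
    x1 = amplitude_matrix(layer1_train)
    y1 = layer1_train[label_col].to_numpy()
    if layer1_kind == "coarse_knn":
        layer1 = fit_knn(x1, y1, k=KNN_COARSE_K)
    elif layer1_kind == "linear_discriminant":
        layer1 = fit_discriminant(x1, y1)
    else:
        raise InputError(f"unknown layer1_kind {layer1_kind!r}")
    mocks = make_training_mocks(layer2_train, spec, label_col=label_col)
    comps = np.stack([composition_features(m, layer1) for m in mocks])
    labels = np.array([m.sample_label for m in mocks])
    layer2 = fit_knn(comps, labels, k=KNN_COARSE_K)
    return TwoLayerModel(layer1=layer1, layer2=layer2,
                         class_order=layer1.class_order.copy(), spec=spec,
                         layer1_kind=layer1_kind, label_col=label_col)


def predict_sample(model: TwoLayerModel, mock: MockExperiment):
    """Predict one mock experiment's sample label and layer-2 score vector."""
    comp = composition_features(mock, model.layer1)
    labels, scores = predict_knn(model.layer2, comp[None, :])
    return labels[0], scores[0]


# ---------------------------------------------------------------------------
# Serialization (JSON; floats round-trip exactly via repr)
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = ("class_order", "feature_mean", "feature_scale", "train_z",
                 "train_labels_idx", "class_means", "pooled_cov",
                 "pooled_cov_inv", "priors")


def _layer_to_dict(m: Layer1Model) -> dict:
    out: dict = {"kind": m.kind, "k": m.k}
    for name in _ARRAY_FIELDS:
        v = getattr(m, name)
        out[name] = None if v is None else np.asarray(v).tolist()
    return out


def _layer_from_dict(d: dict) -> Layer1Model:
    kw: dict = {"kind": d["kind"], "k": d["k"]}
    for name in _ARRAY_FIELDS:
        v = d[name]
        if v is None:
            kw[name] = None
        elif name == "train_labels_idx":
            kw[name] = np.asarray(v, dtype=int)
        elif name == "class_order":
            kw[name] = np.asarray(v)
        else:
            kw[name] = np.asarray(v, dtype=float)
    return Layer1Model(**kw)


def save_model(model: TwoLayerModel, path) -> None:
    """Serialize a fitted two-layer model to JSON."""
    doc = {
        "format": "impedquant.two_layer_model/1",
        "layer1": _layer_to_dict(model.layer1),
        "layer2": _layer_to_dict(model.layer2),
        "class_order": np.asarray(model.class_order).tolist(),
        "spec": asdict(model.spec),
        "layer1_kind": model.layer1_kind,
        "label_col": model.label_col,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> TwoLayerModel:
    """Load a model written by :func:`save_model`."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "impedquant.two_layer_model/1":
        raise InputError(f"{path} is not an impedquant two-layer model file")
    return TwoLayerModel(
        layer1=_layer_from_dict(doc["layer1"]),
        layer2=_layer_from_dict(doc["layer2"]),
        class_order=np.asarray(doc["class_order"]),
        spec=SplitSpec(**doc["spec"]),
        layer1_kind=doc["layer1_kind"],
        label_col=doc["label_col"])
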