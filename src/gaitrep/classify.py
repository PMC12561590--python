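"""KNN classification with stratified cross-validation and metrics.

Evaluation follows the standard small-dataset protocol: stratified K-fold
(default 5) cross-validation where, within each fold, the per-class PCA
reducer is fitted on the training portion only (no test leakage), the
neighbor count k is chosen from a grid by an inner 3-fold validation, and
the held-out fold is predicted with the selected k. Predictions are pooled
over folds before computing metrics.

Metrics: overall accuracy, per-class true positive rate (sensitivity /
recall), positive predictive value (precision), F1, one-vs-rest AUC from
the KNN vote fractions, support-weighted averages of each, and the
confusion matrix in fixed class order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .features import FeatureVector, fit_reducer, reduce_features

__all__ = [
    "MetricsReport",
    "knn_predict",
    "compute_metrics",
    "cross_validate",
]

DEFAULT_K_GRID = (1, 3, 5, 7, 9)


@dataclass
class MetricsReport:
    class_order: list[str]
    accuracy: float
    confusion: np.ndarray
    per_class: dict            # class -> {"TPR","PPV","F1","AUC","support"}
    weighted: dict             # {"TPR","PPV","F1","AUC"}
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "class_order": self.class_order,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "weighted": self.weighted,
            "flags": self.flags,
        }


def knn_predict(
    X_train: np.ndarray,
    y_train,
    X_test: np.ndarray,
    k: int = 5,
    metric: str = "euclidean",
    class_order: list[str] | None = None,
):
    """Majority-vote K-nearest-neighbor prediction.

    Returns ``(labels, scores, class_order)`` where ``scores[i, j]`` is the
    fraction of the k neighbors of test point i labeled
    ``class_order[j]`` (used downstream for AUC). Vote ties are broken by
    the smallest mean neighbor distance among the tied classes, then by
    class order.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= X_train.shape[0]:
        raise ValueError(f"k={k} out of range for {X_train.shape[0]} training points")
    if class_order is None:
        class_order = sorted(set(y_train.tolist()))
    idx_of = {c: i for i, c in enumerate(class_order)}

    nn = NearestNeighbors(n_neighbors=k, metric=metric).fit(X_train)
    dist, ind = nn.kneighbors(X_test)

    scores = np.zeros((X_test.shape[0], len(class_order)))
    labels = []
    for i in range(X_test.shape[0]):
        neigh = y_train[ind[i]]
        for c in neigh:
            scores[i, idx_of[c]] += 1.0 / k
        best = scores[i].max()
        tied = [c for c in class_order if np.isclose(scores[i, idx_of[c]], best)]
        if len(tied) > 1:
            mean_d = {
                c: dist[i][neigh == c].mean() for c in tied
            }
            tied.sort(key=lambda c: (mean_d[c], class_order.index(c)))
        labels.append(tied[0])
    return np.asarray(labels), scores, class_order


def compute_metrics(y_true, y_pred, scores=None, class_order=None) -> MetricsReport:
    """Pooled classification metrics.

    ``scores`` (rows summing to 1 over ``class_order``) enables the
    one-vs-rest AUC; without it AUC is reported as ``None``. A class absent
    from the true labels gets an undefined AUC (excluded from the weighted
    average, flagged); undefined PPV (empty predicted column) is reported
    as 0 with a flag.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if class_order is None:
        class_order = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    conf = confusion_matrix(y_true, y_pred, labels=class_order)
    total = conf.sum()
    accuracy = float(np.trace(conf) / total) if total else 0.0

    flags: list[str] = []
    per_class: dict = {}
    for i, c in enumerate(class_order):
        support = int(conf[i].sum())
        tp = int(conf[i, i])
        col = int(conf[:, i].sum())
        tpr = tp / support if support else 0.0
        if support == 0:
            flags.append(f"class {c}: no true samples, TPR undefined (0)")
        ppv = tp / col if col else 0.0
        if col == 0:
            flags.append(f"class {c}: never predicted, PPV undefined (0)")
        f1 = 2 * ppv * tpr / (ppv + tpr) if (ppv + tpr) else 0.0
        auc = None
        if scores is not None and support and support < total:
            auc = float(roc_auc_score((y_true == c).astype(int), scores[:, i]))
        elif scores is not None:
            flags.append(f"class {c}: AUC undefined")
        per_class[c] = {"TPR": tpr, "PPV": ppv, "F1": f1, "AUC": auc, "support": support}

    supports = np.array([per_class[c]["support"] for c in class_order], dtype=float)
    weighted = {}
    for m in ("TPR", "PPV", "F1"):
        vals = np.array([per_class[c][m] for c in class_order])
        weighted[m] = float((vals * supports).sum() / supports.sum()) if supports.sum() else 0.0
    auc_pairs = [
        (per_class[c]["AUC"], per_class[c]["support"])
        for c in class_order
        if per_class[c]["AUC"] is not None
    ]
    if auc_pairs:
        av, aw = zip(*auc_pairs)
        weighted["AUC"] = float(np.average(av, weights=aw))
    else:
        weighted["AUC"] = None

    return MetricsReport(
        class_order=list(class_order),
        accuracy=accuracy,
        confusion=conf,
        per_class=per_class,
        weighted=weighted,
        flags=flags,
    )


def _select_k(X, y, P, k_grid, seed, inner_folds=3):
    """Pick k by inner stratified CV accuracy (ties -> smaller k)."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    n_splits = min(inner_folds, counts.min())
    if n_splits < 2:
        return k_grid[0]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    acc = {k: [] for k in k_grid}
    for tr, va in skf.split(X, y):
        model = fit_reducer(X[tr], y[tr], P=P)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Rtr = np.stack([reduce_features(x, model) for x in X[tr]])
            Rva = np.stack([reduce_features(x, model) for x in X[va]])
        for k in k_grid:
            if k > len(tr):
                continue
            pred, _, _ = knn_predict(Rtr, y[tr], Rva, k=k)
            acc[k].append(float((pred == y[va]).mean()))
    means = {k: np.mean(v) for k, v in acc.items() if v}
    best = max(means.values())
    return min(k for k, m in means.items() if np.isclose(m, best))


def cross_validate(
    samples,
    labels=None,
    P: int = 15,
    k_grid=DEFAULT_K_GRID,
    n_folds: int = 5,
    seed: int = 0,
    metric: str = "euclidean",
) -> MetricsReport:
    """Stratified K-fold evaluation of the reduce-then-KNN pipeline.

    ``samples`` is a list of labeled :class:`FeatureVector` or a feature
    matrix with ``labels``. Per fold, the reducer is fitted on the training
    portion only and k is chosen by inner validation; predictions are
    pooled over folds. Deterministic given ``seed``.
    """
    if labels is None:
        X = np.stack([s.values for s in samples])
        labels = np.asarray([s.label for s in samples])
    else:
        X = np.asarray(samples, dtype=float)
        labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < n_folds]
    if small.size:
        raise ValueError(f"classes smaller than {n_folds} samples: {small.tolist()}")
    class_order = sorted(classes.tolist())

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(labels), dtype=labels.dtype)
    scores = np.zeros((len(labels), len(class_order)))
    tested = np.zeros(len(labels), dtype=bool)
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        k = _select_k(X[tr], labels[tr], P, k_grid, seed=seed + fold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_reducer(X[tr], labels[tr], P=P)
            Rtr = np.stack([reduce_features(x, model) for x in X[tr]])
            Rte = np.stack([reduce_features(x, model) for x in X[te]])
        pred, sc, _ = knn_predict(Rtr, labels[tr], Rte, k=k, metric=metric,
                                  class_order=class_order)
        y_pred[te] = pred
        scores[te] = sc
        tested[te] = True
    assert tested.all(), "cross-validation folds do not partition the data"
    return compute_metrics(labels, y_pred, scores, class_order)
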