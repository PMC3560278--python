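"""SVM classification of colony scatter patterns and Table-style reporting.

Features are standardized with training-set statistics only, then fed to
a support vector machine (linear kernel, C = 1 by default — 161-dim
moment features with modest sample counts are typically linearly
separable, and a linear margin keeps the model reproducible and
inspectable; an RBF kernel is available through the hyperparameters).

Evaluation reports the 2×2 confusion matrix between the human-assigned
class (rows) and the system's call (columns), with per-class
"distinguish rates": each row normalized to percent, so the diagonal is
the per-class recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import svm

from .features import FeatureVector

__all__ = [
    "SVMHyperparams",
    "TrainedModel",
    "EvaluationReport",
    "train",
    "predict",
    "evaluate",
    "cross_validate",
]

CLASS_ORDER = ("good", "bad")


@dataclass(frozen=True)
class SVMHyperparams:
    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")


@dataclass
class TrainedModel:
    """Fitted SVM stored as plain arrays (JSON-portable).

    Holds the per-feature standardization statistics, the support-vector
    expansion of the decision function, and the feature identities, so a
    saved model predicts bit-identically after a round trip.
    """

    kernel: str
    C: float
    gamma_value: float
    classes: list[str]
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_ids: list[tuple[int, int]] | None
    training_accuracy: float

    @property
    def n_features(self) -> int:
        return self.scaler_mean.size


@dataclass
class EvaluationReport:
    """Confusion counts and row-percent distinguish rates."""

    class_order: list[str]
    confusion: np.ndarray  # rows: true class, cols: predicted
    rates: np.ndarray  # row percentages
    n_test: int

    def per_class_recall(self) -> dict[str, float]:
        return {c: float(self.rates[i, i]) for i, c in enumerate(self.class_order)}

    def to_text(self) -> str:
        """Human-readable distinguish-rate table (rates to one decimal)."""
        header = "True class      " + "".join(f"{c:>12}" for c in self.class_order)
        lines = [header]
        for i, c in enumerate(self.class_order):
            cells = "".join(f"{self.rates[i, j]:>11.1f}%" for j in range(len(self.class_order)))
            lines.append(f"{c:<16}" + cells)
        lines.append(f"n_test = {self.n_test}")
        return "\n".join(lines)


def _xy(vectors) -> tuple[np.ndarray, list[str]]:
    X = np.vstack([np.asarray(v.values, dtype=float) for v in vectors])
    labels = [v.label for v in vectors]
    if any(lab is None for lab in labels):
        raise ValueError("all feature vectors must carry a class label")
    return X, labels


def _class_order(labels) -> list[str]:
    present = set(labels)
    ordered = [c for c in CLASS_ORDER if c in present]
    ordered += sorted(present - set(CLASS_ORDER))
    return ordered


def train(vectors, hyperparams: SVMHyperparams = SVMHyperparams()) -> TrainedModel:
    """Standardize features on the training set and fit the SVM."""
    X, labels = _xy(vectors)
    classes = _class_order(labels)
    if len(classes) < 2:
        raise ValueError("training requires samples from two classes")
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training samples")

    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    clf = svm.SVC(kernel=hyperparams.kernel, C=hyperparams.C, gamma=hyperparams.gamma)
    y = np.array([classes.index(lab) for lab in labels])
    clf.fit(Xs, y)
    if hyperparams.kernel == "rbf":
        if hyperparams.gamma == "scale":
            var = Xs.var()
            gamma_value = 1.0 / (Xs.shape[1] * var) if var > 0 else 1.0
        elif hyperparams.gamma == "auto":
            gamma_value = 1.0 / Xs.shape[1]
        else:
            gamma_value = float(hyperparams.gamma)
    else:
        gamma_value = 0.0

    model = TrainedModel(
        kernel=hyperparams.kernel,
        C=hyperparams.C,
        gamma_value=float(gamma_value),
        classes=classes,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        scaler_mean=mean,
        scaler_scale=scale,
        feature_ids=list(vectors[0].feature_ids) if vectors[0].feature_ids else None,
        training_accuracy=0.0,
    )
    model.training_accuracy = float(
        np.mean(np.array(predict(model, vectors)) == np.array(labels))
    )
    return model


def decision_function(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """SVM decision values from the stored support-vector expansion."""
    Xs = (np.atleast_2d(np.asarray(X, dtype=float)) - model.scaler_mean) / model.scaler_scale
    if model.kernel == "linear":
        K = Xs @ model.support_vectors.T
    else:
        d2 = (
            (Xs**2).sum(axis=1)[:, None]
            - 2.0 * Xs @ model.support_vectors.T
            + (model.support_vectors**2).sum(axis=1)[None, :]
        )
        K = np.exp(-model.gamma_value * d2)
    return K @ model.dual_coef + model.intercept


def predict(model: TrainedModel, vectors) -> list[str]:
    """Predict a class label per feature vector (deterministic)."""
    X = np.vstack([np.asarray(v.values, dtype=float) for v in vectors])
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    dec = decision_function(model, X)
    return [model.classes[1] if d > 0 else model.classes[0] for d in dec]


def evaluate(model: TrainedModel, vectors) -> EvaluationReport:
    """Confusion matrix and per-class distinguish rates on a labeled set."""
    if len(vectors) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    _, labels = _xy(vectors)
    predicted = predict(model, vectors)
    return report_from_labels(labels, predicted, class_order=model.classes)


def report_from_labels(true_labels, predicted_labels, class_order=None) -> EvaluationReport:
    """Build an EvaluationReport from paired label sequences."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    order = list(class_order) if class_order else _class_order(true_labels + predicted_labels)
    k = len(order)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        confusion[order.index(t), order.index(p)] += 1
    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(row_sums > 0, 100.0 * confusion / row_sums, 0.0)
    return EvaluationReport(
        class_order=order, confusion=confusion, rates=rates, n_test=len(true_labels)
    )


def cross_validate(
    vectors,
    k_folds: int = 5,
    seed: int | None = None,
    hyperparams: SVMHyperparams = SVMHyperparams(),
) -> dict:
    """Stratified k-fold cross-validation of the full train/predict chain.

    Standardization and fitting happen inside each fold (no leakage).
    Returns per-fold and aggregate per-class recalls plus overall
    accuracy; fold assignment is deterministic in ``seed``.
    """
    from sklearn.model_selection import StratifiedKFold

    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    _, labels = _xy(vectors)
    counts = {c: labels.count(c) for c in set(labels)}
    if min(counts.values()) < k_folds:
        raise ValueError(
            f"smallest class ({min(counts.values())} samples) cannot fill {k_folds} folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    order = _class_order(labels)
    fold_rates, fold_acc, assignments = [], [], np.empty(len(labels), dtype=int)
    y = np.array(labels)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), y)):
        assignments[te] = fold
        model = train([vectors[i] for i in tr], hyperparams)
        rep = evaluate(model, [vectors[i] for i in te])
        fold_rates.append([rep.per_class_recall().get(c, np.nan) for c in order])
        fold_acc.append(np.trace(rep.confusion) / rep.n_test)
    fold_rates = np.array(fold_rates)
    return {
        "class_order": order,
        "fold_recall": fold_rates,
        "mean_recall": fold_rates.mean(axis=0),
        "sd_recall": fold_rates.std(axis=0, ddof=1),
        "fold_accuracy": np.array(fold_acc),
        "mean_accuracy": float(np.mean(fold_acc)),
        "fold_assignment": assignments,
    }
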