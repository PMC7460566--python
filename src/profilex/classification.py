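"""Binary classifier bank and the confusion-matrix quality criteria.

Four classifiers probe the resolving ability of a gene subset: logistic
regression (GLM), a linear-kernel SVM with cross-validated cost, a single
decision tree (CART) and a 10-tree random forest (RF).  Evaluation follows
the standard confusion-matrix criteria with tumor = positive class:

    AC  = (TP + TN) / (TP + FP + TN + FN)
    PR  = TP / (TP + FP),  RC = TP / (TP + FN),  F = 2 PR RC / (PR + RC)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus the area under the ROC curve in its Mann-Whitney formulation (the
probability that a random tumor sample outscores a random healthy one, ties
counted one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import SampleLabels

__all__ = [
    "ConfusionMatrix",
    "ClassifierMetrics",
    "TrainedModel",
    "CLASSIFIER_KINDS",
    "stratified_split",
    "train_classifier",
    "confusion",
    "metrics",
    "f_measure",
    "roc_auc",
]

CLASSIFIER_KINDS = ("GLM", "SVM", "CART", "RF")

DEFAULT_SVM_COST_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ConfusionMatrix:
    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


@dataclass
class ClassifierMetrics:
    AC: float
    PR: float
    RC: float
    F: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "AC": self.AC, "PR": self.PR, "RC": self.RC,
            "F": self.F, "MCC": self.MCC, "AUC": self.AUC,
        }


@dataclass
class TrainedModel:
    """A fitted binary classifier exposing a tumor-probability score.

    ``predict`` is defined from the score (1 iff score >= 0.5) so the score
    and the hard decision can never disagree.
    """

    kind: str
    estimator: object

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score_samples(X) >= 0.5).astype(int)


def stratified_split(
    labels: SampleLabels, train_frac: float = 0.6, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Per-class random split into train/test id lists.

    The per-class training count is round-half-up of ``train_frac`` times the
    class size (65 healthy + 91 tumor at 0.6 gives 39 + 55 = 94 training
    samples).  Deterministic for a given seed.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in (0, 1):
        members = [s for s, c in labels.mapping.items() if c == cls]
        if len(members) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_train = int(np.floor(train_frac * len(members) + 0.5))  # half-up
        n_train = min(max(n_train, 1), len(members) - 1)
        order = rng.permutation(len(members))
        train_ids.extend(members[i] for i in order[:n_train])
        test_ids.extend(members[i] for i in order[n_train:])
    return train_ids, test_ids


def train_classifier(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    svm_cost_grid: tuple[float, ...] = DEFAULT_SVM_COST_GRID,
    svm_cv_folds: int = 10,
    rf_estimators: int = 10,
) -> TrainedModel:
    """Fit one of the four classifier kinds on a samples x genes matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if kind == "GLM":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif kind == "SVM":
        folds = int(min(svm_cv_folds, counts.min()))
        base = SVC(kernel="linear", probability=True, random_state=seed)
        if folds >= 2:
            est = GridSearchCV(base, {"C": list(svm_cost_grid)}, cv=folds)
        else:
            est = base
    elif kind == "CART":
        est = DecisionTreeClassifier(random_state=seed)
    elif kind == "RF":
        est = RandomForestClassifier(n_estimators=rf_estimators, random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    est.fit(X, y)
    return TrainedModel(kind=kind, estimator=est)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Tally the confusion matrix with tumor (1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    for name, arr in (("truth", y_true), ("prediction", y_pred)):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"{name} labels outside {{0, 1}}: {sorted(bad)}")
    return ConfusionMatrix(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is 0/0; using 0 by convention")
        return 0.0
    return num / den


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    return _safe_ratio(2.0 * precision * recall, precision + recall, "F")


def metrics(cm: ConfusionMatrix) -> ClassifierMetrics:
    """Accuracy, precision, recall, F and MCC from one confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    ac = (cm.TP + cm.TN) / cm.total
    pr = _safe_ratio(cm.TP, cm.TP + cm.FP, "precision")
    rc = _safe_ratio(cm.TP, cm.TP + cm.FN, "recall")
    f = f_measure(pr, rc)
    denom2 = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    if denom2 == 0:
        warnings.warn("MCC denominator is 0; using 0 by convention")
        mcc = 0.0
    else:
        mcc = (cm.TP * cm.TN - cm.FP * cm.FN) / np.sqrt(denom2)
    return ClassifierMetrics(AC=ac, PR=pr, RC=rc, F=f, MCC=float(mcc))


def roc_auc(
    y_true: np.ndarray, scores: np.ndarray
) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney, ties one half) and the ROC points.

    Returns ``(auc, points)`` where ``points`` is an array of (FPR, TPR) rows,
    one per distinct score threshold plus the two trivial endpoints.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("score/truth length mismatch")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC analysis")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks handle ties
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    points = np.empty((thresholds.size + 1, 2))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        points[i, 0] = np.sum(pred & (y_true == 0)) / n_neg
        points[i, 1] = np.sum(pred & (y_true == 1)) / n_pos
    points[-1] = (1.0, 1.0)
    return float(auc), points
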