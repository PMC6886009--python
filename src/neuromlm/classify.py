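"""Diagnostic classification from subject loadings.

A linear discriminant analysis (LDA) classifier is trained on the
per-rank subject loadings and evaluated with stratified k-fold
cross-validation (k = 2), repeated 100 times; the accuracy distribution
over repeats is summarized by its median and quartiles.  Classifier
performance is also reported as an ROC curve and AUC with the
schizophrenia group as the positive class.  Folds are stratified so a
training fold can never lose a whole class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

POSITIVE_LABEL = "schizophrenia"


@dataclass
class LdaModel:
    """Fitted two-class linear discriminant: decision = sign(w'x + b)."""

    weights: np.ndarray
    bias: float
    priors: np.ndarray
    covariance: np.ndarray  # pooled within-class covariance
    classes: np.ndarray
    estimator: LinearDiscriminantAnalysis

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(x) > 0, self.classes[1], self.classes[0])


def lda_train(features: np.ndarray, labels: np.ndarray) -> LdaModel:
    """Train a Fisher/Gaussian linear discriminant with pooled
    covariance and empirical priors."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.ndim == 2 and x.shape[0] == 1 and len(labels) > 1:
        x = x.T
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training members")
    est = LinearDiscriminantAnalysis(solver="svd", store_covariance=True)
    est.fit(x, labels)
    return LdaModel(
        weights=est.coef_[0].copy(),
        bias=float(est.intercept_[0]),
        priors=est.priors_.copy(),
        covariance=est.covariance_.copy(),
        classes=est.classes_.copy(),
        estimator=est,
    )


@dataclass
class ClassificationResult:
    """Repeated-CV accuracy distribution plus ROC/AUC summaries."""

    accuracies: np.ndarray
    median: float
    q25: float
    q75: float
    roc_points: np.ndarray          # (n, 2) FPR, TPR from held-out scores
    auc: float
    roc_points_insample: np.ndarray
    auc_insample: float
    positive_label: str
    k: int
    repeats: int
    seed: int
    cv_scores: np.ndarray = field(default=None)  # held-out discriminant values

    def summary(self) -> dict:
        return {
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "auc": self.auc,
            "auc_insample": self.auc_insample,
            "positive_label": self.positive_label,
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
        }


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_label=POSITIVE_LABEL,
) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoid AUC with ties averaged (Mann-Whitney).

    Constant scores yield the chance diagonal and AUC 0.5 (logged).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_label
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0.0:
        log.warning("constant discriminant scores; AUC set to 0.5")
        curve = np.array([[0.0, 0.0], [1.0, 1.0]])
        return curve, 0.5
    fpr, tpr, _ = _roc_curve(y, scores)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


def _positive_scores(model: LdaModel, x: np.ndarray, positive_label) -> np.ndarray:
    s = model.decision_function(x)
    return s if model.classes[1] == positive_label else -s


def repeated_kfold_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 2,
    repeats: int = 100,
    seed: int = 0,
    positive_label=None,
) -> ClassificationResult:
    """Repeated stratified k-fold cross-validated accuracy.

    Each repeat draws a fresh stratified split into k folds; accuracy is
    pooled correct/total over the held-out folds, giving one number per
    repeat.  Percentiles use the linear-interpolation quantile
    definition.  The ROC is computed from the held-out discriminant
    scores of the first repeat (an in-sample ROC is also emitted,
    labeled as such).  Fully deterministic given ``seed``.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smallest class size {counts.min()}")
    if positive_label is None:
        positive_label = POSITIVE_LABEL if POSITIVE_LABEL in classes else classes[-1]

    rng = np.random.default_rng(seed)
    idx = np.arange(len(labels))
    accuracies = np.empty(repeats)
    cv_scores = np.empty(len(labels))
    for rep in range(repeats):
        for attempt in range(100):
            state = int(rng.integers(0, 2**31 - 1))
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
            folds = list(skf.split(x, labels))
            ok = all(
                np.unique(labels[tr], return_counts=True)[1].min() >= 2
                for tr, _ in folds
            )
            if ok:
                break
            log.warning("fold with a near-empty class; resampling split")
        else:  # pragma: no cover - unreachable with stratification
            raise RuntimeError("could not draw valid folds")
        correct = 0
        for train, test in folds:
            model = lda_train(x[train], labels[train])
            pred = model.predict(x[test])
            correct += int((pred == labels[test]).sum())
            if rep == 0:
                cv_scores[test] = _positive_scores(model, x[test], positive_label)
        accuracies[rep] = correct / len(labels)

    q25, med, q75 = np.percentile(accuracies, [25, 50, 75])
    roc_cv, auc_cv = roc_auc(cv_scores, labels, positive_label)
    full = lda_train(x, labels)
    roc_in, auc_in = roc_auc(
        _positive_scores(full, x, positive_label), labels, positive_label
    )
    return ClassificationResult(
        accuracies=accuracies,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        roc_points=roc_cv,
        auc=auc_cv,
        roc_points_insample=roc_in,
        auc_insample=auc_in,
        positive_label=str(positive_label),
        k=k,
        repeats=repeats,
        seed=seed,
        cv_scores=cv_scores,
    )
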