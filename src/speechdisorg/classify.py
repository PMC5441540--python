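"""Cross-validated Naive Bayes classification of diagnosis and symptom severity.

Two binary targets are supported: the schizophrenia diagnosis (against the
pooled bipolar + control groups) and negative-symptom severity, obtained
by a median split of PANSS negative totals over the psychotic patients
only (high = strictly above the median, low = at or below). Features are
either the connectedness attribute panel or the one-dimensional
Disorganization Index.

The classifier is Gaussian naive Bayes with empirical class priors,
refit inside each training fold of a seeded stratified k-fold (10 folds
by default). Out-of-fold posterior probabilities are pooled into a single
ROC, so the AUC is the Mann-Whitney rank statistic on the pooled
posteriors; confusion-matrix metrics use the 0.5 posterior threshold.
Specificity is reported as the standard true-negative rate. Per-class
(positive) and class-weighted averages of sensitivity/specificity are
both emitted, since published tables differ in which convention they use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

__all__ = [
    "SeverityLabels",
    "ClassificationReport",
    "median_split",
    "naive_bayes_cv",
    "evaluate",
]


@dataclass(frozen=True)
class SeverityLabels:
    """Binary high/low severity labels from a median split of patient scores."""

    labels: tuple[str, ...]
    cutoff: float

    def as_binary(self) -> np.ndarray:
        return np.array([1 if l == "high" else 0 for l in self.labels], dtype=int)


def median_split(scores) -> SeverityLabels:
    """Split patient symptom scores at the sample median.

    high = strictly greater than the median; low = less than or equal.
    Controls must not be included in ``scores`` (the cutoff is defined over
    psychotic patients only). Even n uses the mean-of-middle-values median.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores for a median split")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; median split needs complete scores")
    cutoff = float(np.median(scores))
    labels = tuple("high" if s > cutoff else "low" for s in scores)
    if all(l == "low" for l in labels):
        warnings.warn(
            "degenerate split: no score exceeds the median (all labeled low)",
            UserWarning,
        )
    return SeverityLabels(labels=labels, cutoff=cutoff)


@dataclass
class ClassificationReport:
    """Metric panel for one cross-validated binary classification."""

    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f_measure: float
    auc: float
    accuracy_percent: float
    weighted_sensitivity: float
    weighted_specificity: float
    n: int
    folds: int
    seed: int | None
    per_fold: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "accuracy_percent": self.accuracy_percent,
            "weighted_sensitivity": self.weighted_sensitivity,
            "weighted_specificity": self.weighted_specificity,
            "n": self.n,
            "folds": self.folds,
            "seed": self.seed,
        }


def evaluate(
    posteriors,
    truth,
    *,
    threshold: float = 0.5,
    folds: int = 0,
    seed: int | None = None,
    per_fold: list[dict] | None = None,
) -> ClassificationReport:
    """Deterministic metric panel from pooled posteriors and ground truth."""
    p = np.asarray(posteriors, dtype=float)
    y = np.asarray(truth, dtype=int)
    if p.shape != y.shape:
        raise ValueError("posteriors and truth lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("truth contains a single class: AUC undefined")
    pred = (p > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else 0.0
    recall = sens
    f1 = 2 * prec * recall / (prec + recall) if prec + recall else 0.0
    n_pos, n_neg = tp + fn, tn + fp
    # class-weighted averages: each class's own recall / own true-negative rate
    w_sens = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    w_spec = (spec * n_pos + sens * n_neg) / (n_pos + n_neg)
    auc = float(roc_auc_score(y, p))
    acc = 100.0 * (tp + tn) / y.size
    return ClassificationReport(
        sensitivity=float(sens),
        specificity=float(spec),
        precision=float(prec),
        recall=float(recall),
        f_measure=float(f1),
        auc=auc,
        accuracy_percent=float(acc),
        weighted_sensitivity=float(w_sens),
        weighted_specificity=float(w_spec),
        n=int(y.size),
        folds=folds,
        seed=seed,
        per_fold=per_fold or [],
    )


def naive_bayes_cv(
    features,
    labels,
    folds: int = 10,
    seed: int | None = 0,
) -> ClassificationReport:
    """Gaussian naive Bayes with seeded stratified k-fold cross-validation.

    Class priors and class-conditional Gaussians are re-estimated inside
    each training fold; out-of-fold posterior probabilities for the
    positive class are pooled and passed to :func:`evaluate`. If the
    minority class is smaller than ``folds``, the fold count is reduced to
    that size (stratification then guarantees both classes in every
    training fold).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("features and labels lengths differ")
    counts = np.bincount(y, minlength=2)
    if (counts == 0).any():
        raise ValueError("both classes must be present")
    if y.size < folds:
        raise ValueError(f"need at least {folds} observations for {folds}-fold CV")
    eff_folds = min(folds, int(counts.min()))
    if eff_folds < folds:
        warnings.warn(
            f"minority class has {counts.min()} members: folds reduced to {eff_folds}",
            UserWarning,
        )
    if eff_folds < 2:
        raise ValueError("minority class too small for cross-validation")
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    posterior = np.empty(y.size, dtype=float)
    per_fold: list[dict] = []
    for k, (train, test) in enumerate(skf.split(X, y)):
        clf = GaussianNB()  # variance smoothing 1e-9 * max feature variance
        clf.fit(X[train], y[train])
        pos_col = int(np.where(clf.classes_ == 1)[0][0])
        p = clf.predict_proba(X[test])[:, pos_col]
        posterior[test] = p
        correct = int(np.sum((p > 0.5).astype(int) == y[test]))
        per_fold.append({"fold": k, "n": int(test.size), "correct": correct})
    return evaluate(posterior, y, folds=eff_folds, seed=seed, per_fold=per_fold)
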