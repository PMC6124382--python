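"""Classifier-based evaluation of signatures.

Since the selectors do not estimate coefficients for the selected
features, a probabilistic classifier (by default a linear-kernel SVM with
Platt probability calibration) is fitted per time point on that time
point's selected features; the resulting posteriors are scored per time
point and after averaging over time points. Metrics: misclassification
error, generalized Brier score (GBS, 0 optimal), belief confusion metric
(BCM, 1 optimal) and area under the precision-recall curve (AUPR, 1
optimal), all bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_model import LongitudinalExpressionSet, Signature

__all__ = [
    "MetricsReport",
    "fit_posteriors",
    "average_posteriors",
    "compute_metrics",
    "evaluate_signature",
    "cv_tune_cutoff",
]


@dataclass
class MetricsReport:
    error: float
    gbs: float
    bcm: float
    aupr: float
    scope: str = "averaged"

    def to_dict(self) -> dict:
        return asdict(self)


def _default_classifier(seed: int | None):
    return SVC(kernel="linear", probability=True, random_state=seed)


def fit_posteriors(
    train: LongitudinalExpressionSet,
    signature: Signature,
    test: LongitudinalExpressionSet | None = None,
    classifier_factory=None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Posterior probability of the positive class per (subject, time point).

    One classifier per time point, trained on that time point's selected
    features only. A time point with no selected features yields 0.5 for
    every subject (with a warning). ``test=None`` scores the training set.
    """
    if classifier_factory is None:
        classifier_factory = lambda: _default_classifier(seed)
    target = train if test is None else test
    # a test set may cover fewer time points; only its own columns are scored
    post = pd.DataFrame(index=pd.Index(target.subjects, name="subject"),
                        columns=target.timepoints, dtype=float)
    y_train = train.y
    for tp in target.timepoints:
        genes = signature.genes_at(tp)
        if not genes:
            warnings.warn(f"no selected features at time point {tp!r}; posterior 0.5")
            post[tp] = 0.5
            continue
        gi = [train.gene_index(g) for g in genes]
        j = train.timepoint_index(tp)
        X_train = train.values[gi, :, j].T      # subjects x genes
        jt = target.timepoint_index(tp)
        git = [target.gene_index(g) for g in genes]
        X_target = target.values[git, :, jt].T
        clf = classifier_factory()
        clf.fit(X_train, y_train)
        proba = clf.predict_proba(X_target)
        pos_col = list(clf.classes_).index(1)
        post[tp] = proba[:, pos_col]
    return post


def average_posteriors(posteriors: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of per-time-point posteriors per subject."""
    if posteriors.isna().any().any():
        raise ValueError("posterior table contains missing cells")
    return posteriors.mean(axis=1)


def _aupr(y: np.ndarray, p: np.ndarray) -> float:
    """Area under the precision-recall curve, trapezoidal over recall,
    positive class = 1."""
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last index of each distinct score (threshold semantics)
    keep = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tp, fp = tp[keep], fp[keep]
    n_pos = int(y.sum())
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall = np.r_[0.0, recall]
    precision = np.r_[1.0, precision]
    return float(np.trapezoid(precision, recall))


def compute_metrics(
    posteriors: pd.Series | np.ndarray,
    y: np.ndarray,
    scope: str = "averaged",
) -> MetricsReport:
    """Error / GBS / BCM / AUPR for one posterior vector.

    error: fraction misclassified at threshold 0.5 (ties -> positive);
    GBS = (1/2n) sum_subjects sum_{classes} (p_class - 1{true})^2;
    BCM = mean posterior assigned to the true class.
    """
    p = np.asarray(posteriors, dtype=float)
    y = np.asarray(y, dtype=int)
    if p.shape != y.shape:
        raise ValueError("posteriors and labels must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("AUPR undefined for a one-class label vector")
    n = len(y)
    pred = (p >= 0.5).astype(int)
    error = float(np.mean(pred != y))
    p_true = np.where(y == 1, p, 1.0 - p)
    gbs = float(np.sum((p - y) ** 2 + ((1 - p) - (1 - y)) ** 2) / (2 * n))
    bcm = float(np.mean(p_true))
    return MetricsReport(error=error, gbs=gbs, bcm=bcm, aupr=_aupr(y, p), scope=scope)


def evaluate_signature(
    train: LongitudinalExpressionSet,
    signature: Signature,
    test: LongitudinalExpressionSet | None = None,
    classifier_factory=None,
    seed: int | None = 0,
) -> dict[str, MetricsReport]:
    """Per-time-point metrics plus metrics on the averaged posteriors."""
    target = train if test is None else test
    post = fit_posteriors(train, signature, test, classifier_factory, seed)
    y = target.y
    out = {
        tp: compute_metrics(post[tp].to_numpy(), y, scope=tp) for tp in post.columns
    }
    out["averaged"] = compute_metrics(average_posteriors(post).to_numpy(), y)
    return out


def cv_tune_cutoff(
    expr: LongitudinalExpressionSet,
    selector,
    grid=(0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5),
    folds: int = 5,
    seed: int | None = 0,
    classifier_factory=None,
) -> tuple[float, dict[float, float]]:
    """Choose the reduction cutoff minimizing mean stratified k-fold CV error.

    ``selector(train_expr, c_cutoff)`` must return a Signature. The CV
    error is computed on the averaged posteriors of the held-out fold.
    Ties go to the smallest cutoff. Returns (chosen cutoff, error per
    grid value).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if len(grid) == 1:
        return grid[0], {grid[0]: float("nan")}
    y = expr.y
    subjects = np.array(expr.subjects)
    splits = None
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=None if seed is None else seed + attempt)
        cand = list(skf.split(subjects, y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
               for tr, te in cand):
            splits = cand
            break
    if splits is None:
        raise ValueError("could not build stratified folds keeping both classes")

    errors: dict[float, float] = {}
    for c in grid:
        fold_err = []
        for tr_idx, te_idx in splits:
            train = expr.subset_subjects(list(subjects[tr_idx]))
            test = expr.subset_subjects(list(subjects[te_idx]))
            sig = selector(train, c)
            if not sig.entries:
                fold_err.append(float(np.mean(test.y != 1)))  # predict-all-positive fallback
                continue
            post = fit_posteriors(train, sig, test,
                                  classifier_factory=classifier_factory, seed=seed)
            avg = average_posteriors(post).to_numpy()
            pred = (avg >= 0.5).astype(int)
            fold_err.append(float(np.mean(pred != test.y)))
        errors[c] = float(np.mean(fold_err))
    best = min(grid, key=lambda c: (errors[c], c))
    return best, errors
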