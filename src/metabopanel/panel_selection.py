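"""Repeated cross-validation, weight-based feature ranking, and minimal
panel selection.

The discovery protocol estimates two things at once from a labelled
feature table by repeated stratified 4-fold cross-validation:

* held-out performance (accuracy, sensitivity, specificity), summarized
  as the mean over iterations with a normal-approximation 95% CI of the
  mean, and
* per-feature importance — the mean of squared SVM weights over every
  fold-model fitted (sign-robust across refits).

Features are ranked by importance, then nested models are rebuilt on the
top-1, top-2, … top-``max_n`` features (each again by repeated CV) to
trace how accuracy grows with panel size.  The minimal panel is the
shortest prefix whose mean accuracy comes within ``tolerance`` of the
curve's maximum — small panels are what make a targeted assay practical.

Rows are L2-normalized per sample before any fold split; this uses only
each sample's own values and cannot leak across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import svm_core
from .svm_core import l2_normalize, squared_weights, train_linear_svm

Z95 = 1.959964  # normal quantile for a 95% CI of the mean


@dataclass
class CvResult:
    """Summary of repeated stratified k-fold cross-validation."""

    n_iterations: int
    folds: int
    accuracy: np.ndarray  # per-iteration held-out accuracy
    sensitivity: np.ndarray
    specificity: np.ndarray
    train_accuracy: np.ndarray
    importance: np.ndarray  # mean squared weight per feature

    def summary(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "train_accuracy"):
            vals = getattr(self, name)
            mean = float(vals.mean())
            half = Z95 * float(vals.std(ddof=1)) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            out[name] = {"mean": mean, "ci_lower": mean - half, "ci_upper": mean + half}
        return out


@dataclass
class TopNCurve:
    """Mean held-out accuracy as a function of panel size N = 1..max_n."""

    n: np.ndarray
    mean_accuracy: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_iterations: int


def _stratified_assignment(y: np.ndarray, folds: int, rng) -> np.ndarray:
    """Random fold label per sample, stratified by class."""
    assign = np.empty(len(y), dtype=int)
    for cls in (-1, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 4,
    n_iter: int = 2000,
    c: float = 4.0,
    seed: int = 0,
    normalize: bool = True,
    svm_tol: float = 1e-3,
) -> CvResult:
    """Repeated stratified k-fold CV of the linear SVM.

    Each iteration draws a fresh stratified fold assignment; each of the
    ``folds`` models is trained on the remaining folds and scored on the
    held-out fold.  The importance phase of the discovery protocol uses
    ``n_iter=2000, folds=4``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    for cls in (-1, 1):
        if np.sum(y == cls) < folds:
            raise ValueError(f"class {cls:+d} has fewer samples than folds")
    if normalize:
        X = l2_normalize(X)
    rng = np.random.default_rng(seed)
    n, M = X.shape
    acc = np.empty(n_iter)
    sens = np.empty(n_iter)
    spec = np.empty(n_iter)
    tr_acc = np.empty(n_iter)
    importance = np.zeros(M)
    n_models = 0
    for it in range(n_iter):
        assign = _stratified_assignment(y, folds, rng)
        tp = fp = tn = fn = 0
        tr_correct = tr_total = 0
        for k in range(folds):
            test = assign == k
            model = train_linear_svm(X[~test], y[~test], c=c, tol=svm_tol)
            importance += squared_weights(model)
            n_models += 1
            pred = svm_core.predict(model, X[test])
            yt = y[test]
            tp += int(np.sum((pred == 1) & (yt == 1)))
            fn += int(np.sum((pred == -1) & (yt == 1)))
            tn += int(np.sum((pred == -1) & (yt == -1)))
            fp += int(np.sum((pred == 1) & (yt == -1)))
            tr_pred = svm_core.predict(model, X[~test])
            tr_correct += int(np.sum(tr_pred == y[~test]))
            tr_total += int(np.sum(~test))
        acc[it] = (tp + tn) / n
        sens[it] = tp / (tp + fn) if tp + fn else np.nan
        spec[it] = tn / (tn + fp) if tn + fp else np.nan
        tr_acc[it] = tr_correct / tr_total
    return CvResult(
        n_iterations=n_iter,
        folds=folds,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        train_accuracy=tr_acc,
        importance=importance / n_models,
    )


def rank_features(cv: CvResult, feature_ids: list[str] | None = None) -> np.ndarray:
    """Feature order by descending importance; ties break by ascending index.

    Returns integer indices; pass ``feature_ids`` to get ids instead.
    """
    imp = cv.importance
    order = np.lexsort((np.arange(len(imp)), -imp))
    if feature_ids is not None:
        return np.asarray(feature_ids, dtype=object)[order]
    return order


def topn_accuracy_curve(
    X: np.ndarray,
    y: np.ndarray,
    ranking: np.ndarray,
    max_n: int = 100,
    folds: int = 4,
    n_iter: int = 500,
    c: float = 4.0,
    seed: int = 0,
    normalize: bool = True,
    svm_tol: float = 1e-3,
) -> TopNCurve:
    """Accuracy of nested top-N models, N = 1..max_n.

    For each N the top-N ranked features are re-evaluated by repeated CV
    (``n_iter`` iterations each, 500 by default) with the same seed, so
    N = all features reproduces :func:`repeated_cv` on the full table.
    Columns are taken in ascending original index within the subset;
    model performance only depends on the subset, not its order.
    """
    X = np.asarray(X, dtype=float)
    ranking = np.asarray(ranking, dtype=int)
    if max_n > X.shape[1]:
        raise ValueError("max_n exceeds the number of features")
    means = np.empty(max_n)
    lo = np.empty(max_n)
    hi = np.empty(max_n)
    for N in range(1, max_n + 1):
        cols = np.sort(ranking[:N])
        res = repeated_cv(
            X[:, cols], y, folds=folds, n_iter=n_iter, c=c, seed=seed,
            normalize=normalize, svm_tol=svm_tol,
        )
        s = res.summary()["accuracy"]
        means[N - 1] = s["mean"]
        lo[N - 1] = s["ci_lower"]
        hi[N - 1] = s["ci_upper"]
    return TopNCurve(
        n=np.arange(1, max_n + 1),
        mean_accuracy=means,
        ci_lower=lo,
        ci_upper=hi,
        n_iterations=n_iter,
    )


def select_panel(
    curve: TopNCurve,
    ranking: np.ndarray,
    tolerance: float = 0.01,
    availability_mask: np.ndarray | None = None,
    feature_ids: list[str] | None = None,
) -> list:
    """Smallest top-N prefix within ``tolerance`` of the curve's maximum.

    ``availability_mask`` (boolean per feature, indexed like the data
    columns) models the wet-lab filter for standard/MS-MS availability:
    unavailable features are skipped while walking the ranking, *before*
    the curve positions are read — the curve must have been computed on
    the same filtered ranking.
    """
    ranking = np.asarray(ranking)
    if availability_mask is not None:
        availability_mask = np.asarray(availability_mask, dtype=bool)
        if not availability_mask.any():
            raise ValueError("no features available")
        ranking = np.array([f for f in ranking if availability_mask[int(f)]])
    target = curve.mean_accuracy.max() - tolerance
    n_star = int(np.argmax(curve.mean_accuracy >= target)) + 1
    panel = list(ranking[:n_star])
    if feature_ids is not None:
        panel = [feature_ids[int(f)] for f in panel]
    return panel
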