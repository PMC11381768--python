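"""Diagnostic-model metrics, multiple testing, and ratio-marker analysis.

Positive class is case (+1) throughout: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP).  ROC AUC is the trapezoidal area over all
score thresholds, identical to the Mann–Whitney statistic U/(n₊·n₋)
with ties counted one half.  Mean metrics over CV iterations carry a
normal-approximation 95% CI of the mean (±1.96·SD/√n) — the convention
behind the very narrow intervals that thousands of CV iterations give.

Group comparisons default to Welch's unequal-variance t-test, with
Benjamini–Hochberg step-up adjustment across families of tests.  The
ratio-marker analysis evaluates a metabolite concentration ratio (e.g.
inosine/uridine) as a predictor of chemotherapy response within each
breast-cancer subtype: a Welch test on the log-ratio plus a ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from statsmodels.stats.multitest import multipletests

from .tables import ConcentrationTable

Z95 = 1.959964


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_metrics(y_true, y_pred) -> ConfusionSummary:
    """Confusion counts and the three headline fractions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if not (set(np.unique(y_true)) <= {-1, 1} and set(np.unique(y_pred)) <= {-1, 1}):
        raise ValueError("labels must be +1/-1")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == -1)))
    tn = int(np.sum((y_pred == -1) & (y_true == -1)))
    fn = int(np.sum((y_pred == -1) & (y_true == 1)))
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / y_true.size,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
    )


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and trapezoidal AUC (positive class +1).

    Equals the Mann–Whitney U/(n₊·n₋) probability that a random
    positive scores above a random negative, ties counted ½.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(set(np.unique(labels))) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = skm.roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class PrCurve:
    precision: np.ndarray
    recall: np.ndarray
    average_precision: float


def pr_curve(scores, labels) -> PrCurve:
    """Precision–recall curve with average precision (positive class +1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("no positive samples")
    precision, recall, _ = skm.precision_recall_curve(labels, scores, pos_label=1)
    ap = float(skm.average_precision_score(labels, scores, pos_label=1))
    # sklearn returns the curve from high to low threshold; flip so recall
    # is non-decreasing along the curve
    return PrCurve(precision=precision[::-1], recall=recall[::-1],
                   average_precision=ap)


def mean_ci(
    values, level: float = 0.95, method: str = "normal"
) -> tuple[float, float, float]:
    """Mean of CV-iteration metrics with a 95% interval.

    ``method="normal"`` (default) is the CI of the mean, mean ± z·SD/√n —
    the convention behind the very narrow intervals thousands of CV
    iterations produce.  ``method="percentile"`` instead brackets the
    iteration *distribution* by its central quantiles.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(values.mean())
    if method == "percentile":
        alpha = (1.0 - level) / 2
        lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
        return mean, float(lo), float(hi)
    if method != "normal":
        raise ValueError(f"unknown CI method {method!r}")
    z = float(stats.norm.ppf(0.5 + level / 2))
    half = z * float(values.std(ddof=1)) / np.sqrt(values.size)
    return mean, mean - half, mean + half


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def group_difference_test(values, groups, equal_var: bool = False):
    """Two-sample t-test (Welch by default) between the two group labels.

    Returns ``(t, p)``; the first group label in sorted order is the
    first sample, so swapping labels negates t and keeps p.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def ratio_marker_analysis(
    conc: ConcentrationTable,
    numerator: str,
    denominator: str,
    outcome_col: str = "response",
    positive_outcome: str = "non-pCR",
    strata_col: str = "subtype",
) -> pd.DataFrame:
    """Per-stratum predictive value of a concentration ratio.

    For each stratum (subtype): the per-subject ratio
    ``conc[numerator]/conc[denominator]``, a Welch test on the
    log-ratio between outcomes, and the ROC AUC of the ratio with
    ``positive_outcome`` as the positive class.  Subjects with a
    non-positive denominator are excluded with a warning; a stratum
    with a single outcome class gets NaN AUC and p.
    """
    for a in (numerator, denominator):
        if a not in conc.concentrations.columns:
            raise ValueError(f"analyte {a!r} not in the concentration table")
    num = conc.concentrations[numerator]
    den = conc.concentrations[denominator]
    ok = (den > 0) & num.notna() & den.notna()
    if (~ok).any():
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d subject(s) with non-positive/missing denominator",
            int((~ok).sum()),
        )
    ratio = (num[ok] / den[ok]).rename("ratio")
    meta = conc.metadata.loc[ok.index[ok]]
    rows = []
    for stratum, sub in meta.groupby(strata_col, sort=False):
        r = ratio.loc[sub.index]
        outcomes = sub[outcome_col]
        classes = sorted(set(outcomes))
        row = {"stratum": stratum, "n": len(r), "auc": np.nan,
               "t": np.nan, "p": np.nan,
               "mean_ratio": float(r.mean())}
        if len(classes) == 2:
            row["t"], row["p"] = group_difference_test(np.log(r), outcomes)
            y = np.where(outcomes == positive_outcome, 1, -1)
            row["auc"] = roc_auc(r.to_numpy(), y).auc
        rows.append(row)
    return pd.DataFrame(rows)
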