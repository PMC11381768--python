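"""Below-detection imputation and pooled-QC signal-drift correction.

Untargeted LC-MS intensities drift with injection order (source fouling,
detector attenuation).  Pooled QC samples — aliquot mixtures of all study
samples injected periodically — measure that drift directly: any trend in
a feature's QC intensity over the run is instrumental, not biological.
The correction here fits a smooth trend to each feature's QC intensities
versus injection order and divides it out, restoring every injection to
the feature's QC reference level:

    corrected(i, j) = raw(i, j) * reference_j / trend_j(order_i)

Two interchangeable trend fitters are provided: a local-linear (lowess)
smoother and an averaged bootstrap ensemble of piecewise-linear
interpolants over injection order.  Correction is per batch; with
multiple batches, each batch is additionally rescaled to the global QC
reference level so batch offsets are removed together with drift.

A feature is only kept corrected if the correction does not worsen its
QC relative standard deviation; otherwise it is reverted and flagged in
the QC report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .tables import FeatureTable

logger = logging.getLogger(__name__)

TREND_METHODS = ("ensemble_regression", "loess_like")


class TrendFitError(ValueError):
    """The QC trend cannot be fitted; caller should fall back to the
    global-median reference for this feature."""


def feature_rsd(values) -> float:
    """Relative standard deviation (sd/mean) of QC intensities.

    Sample standard deviation (ddof=1).  Requires >= 2 values and a
    nonzero mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Replace missing entries with 1/10 of the feature's minimum peak height.

    The minimum is taken over all present entries of the feature across
    all samples (subjects and QCs alike).  Features with no present
    value cannot be imputed and are dropped with a logged warning.
    """
    intens = table.intensities.copy()
    all_missing = intens.isna().all(axis=0)
    if all_missing.any():
        dropped = list(intens.columns[all_missing])
        logger.warning(
            "dropping %d feature(s) with no present value: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
        intens = intens.loc[:, ~all_missing]
    fill = intens.min(axis=0, skipna=True) / 10.0
    intens = intens.fillna(fill)
    return FeatureTable(intens, table.metadata, list(table.planted_features))


@dataclass
class TrendModel:
    """Fitted QC-intensity trend of one feature over injection order.

    ``grid_orders``/``grid_values`` tabulate the smoothed trend at the QC
    orders; prediction interpolates linearly between them and clamps to
    the nearest QC prediction outside the fitted range (avoids sign
    flips at the sequence edges).  ``reference_level`` is the median QC
    intensity the correction restores.
    """

    feature_id: str
    grid_orders: np.ndarray
    grid_values: np.ndarray
    reference_level: float

    def predict(self, orders) -> np.ndarray:
        orders = np.atleast_1d(np.asarray(orders, dtype=float))
        return np.interp(orders, self.grid_orders, self.grid_values)


def fit_qc_trend(
    qc_intensities,
    qc_orders,
    method: str = "loess_like",
    *,
    feature_id: str = "",
    seed: int = 0,
    n_members: int = 50,
    lowess_frac: float = 0.6,
) -> TrendModel:
    """Fit a smooth QC-intensity trend over injection order.

    ``loess_like`` runs a local-linear (lowess) smoother through the QC
    points; ``ensemble_regression`` averages ``n_members`` bootstrap
    piecewise-linear interpolants (a randomized-regression ensemble in
    the spirit of random-forest QC correction).  Both are exact on
    constant and, for loess, linear QC series.

    Raises
    ------
    TrendFitError
        Fewer than 3 QC points (fall back to the global-median
        reference) or non-positive QC intensities.
    """
    y = np.asarray(qc_intensities, dtype=float)
    x = np.asarray(qc_orders, dtype=float)
    if y.size != x.size:
        raise ValueError("qc_intensities and qc_orders differ in length")
    if y.size < 3:
        raise TrendFitError(
            "need >= 3 QC points to fit a trend; use the global-median fallback"
        )
    if np.any(y <= 0):
        raise TrendFitError("QC intensities must be positive")
    if method not in TREND_METHODS:
        raise ValueError(f"unknown trend method {method!r}")
    order = np.argsort(x)
    x, y = x[order], y[order]

    if method == "loess_like":
        fitted = lowess(
            y, x, frac=lowess_frac, it=0, return_sorted=False
        )
        grid_x, grid_y = x, np.asarray(fitted, dtype=float)
    else:
        rng = np.random.default_rng(seed)
        n = x.size
        grid_x = x
        acc = np.zeros(n)
        for _ in range(n_members):
            idx = np.unique(rng.integers(0, n, size=n))
            # always keep the endpoints so the member spans the range
            idx = np.union1d(idx, [0, n - 1])
            acc += np.interp(grid_x, x[idx], y[idx])
        grid_y = acc / n_members

    reference = float(np.median(y))
    return TrendModel(feature_id, grid_x, grid_y, reference)


def apply_drift_correction(
    table: FeatureTable,
    trends: dict[str, TrendModel],
    metadata: pd.DataFrame | None = None,
) -> FeatureTable:
    """Divide each feature by its fitted QC trend, rescaled to the
    reference level.

    ``trends`` maps feature id to a :class:`TrendModel` fitted on this
    table's (batch's) QCs.  Features without a trend, or whose trend
    predicts a non-positive value at some injection, are left
    uncorrected.  Imputation must already have been applied.
    """
    meta = table.metadata if metadata is None else metadata
    orders = meta["injection_order"].to_numpy(dtype=float)
    intens = table.intensities.copy()
    for fid, model in trends.items():
        if fid not in intens.columns:
            continue
        pred = model.predict(orders)
        if np.any(pred <= 0):
            logger.warning("feature %s: non-positive trend prediction, skipped", fid)
            continue
        intens[fid] = intens[fid].to_numpy() * model.reference_level / pred
    return FeatureTable(intens, table.metadata, list(table.planted_features))


def correct_table(
    table: FeatureTable,
    method: str = "loess_like",
    seed: int = 0,
    min_qc: int = 3,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Full per-batch QC-trend correction of an (imputed) feature table.

    Per batch and feature: fit the QC trend, divide it out, and keep the
    correction only if it does not worsen the feature's QC RSD.  With
    several batches, corrected intensities are harmonized to the global
    (all-batch) QC reference level of each feature.

    Returns the corrected table and a per-feature QC report with columns
    ``feature_id, rsd_before, rsd_after, corrected``.
    """
    meta = table.metadata
    intens = table.intensities.copy()
    if intens.isna().any().any():
        raise ValueError("impute_missing must run before drift correction")
    qc_mask = (meta["role"] == "qc").to_numpy()
    if qc_mask.sum() < min_qc:
        raise TrendFitError("too few QC injections in the table")

    batches = list(dict.fromkeys(meta["batch"]))
    global_ref = intens.loc[qc_mask].median(axis=0)

    corrected = intens.copy()
    corrected_flag = {fid: False for fid in intens.columns}
    for batch in batches:
        b_mask = (meta["batch"] == batch).to_numpy()
        bq = b_mask & qc_mask
        orders_all = meta.loc[b_mask, "injection_order"].to_numpy(dtype=float)
        qc_orders = meta.loc[bq, "injection_order"].to_numpy(dtype=float)
        for fid in intens.columns:
            qc_vals = intens.loc[bq, fid].to_numpy(dtype=float)
            if qc_vals.size < min_qc or np.any(qc_vals <= 0):
                continue
            model = fit_qc_trend(
                qc_vals, qc_orders, method, feature_id=fid, seed=seed
            )
            pred = model.predict(orders_all)
            if np.any(pred <= 0):
                continue
            new_vals = (
                intens.loc[b_mask, fid].to_numpy(dtype=float)
                * model.reference_level
                / pred
            )
            # only keep the correction if it stabilizes the QCs
            old_rsd = feature_rsd(qc_vals)
            new_qc = qc_vals * model.reference_level / model.predict(qc_orders)
            if feature_rsd(new_qc) <= old_rsd + 1e-9:
                corrected.loc[b_mask, fid] = new_vals
                corrected_flag[fid] = True
        if len(batches) > 1:
            # harmonize this batch to the global QC reference level
            batch_ref = corrected.loc[bq].median(axis=0)
            scale = global_ref / batch_ref
            corrected.loc[b_mask] = corrected.loc[b_mask] * scale

    rows = []
    for fid in intens.columns:
        before = intens.loc[qc_mask, fid].to_numpy(dtype=float)
        after = corrected.loc[qc_mask, fid].to_numpy(dtype=float)
        rows.append(
            {
                "feature_id": fid,
                "rsd_before": feature_rsd(before),
                "rsd_after": feature_rsd(after),
                "corrected": "yes" if corrected_flag[fid] else "no",
            }
        )
    report = pd.DataFrame(rows)
    out = FeatureTable(corrected, table.metadata, list(table.planted_features))
    return out, report
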