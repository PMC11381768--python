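"""SIL-IS calibration and absolute quantification of targeted runs.

Targeted (MRM) quantification measures, for every injection, the peak
area of each analyte and of its stable-isotope-labelled internal
standard (SIL-IS) spiked at a fixed amount.  The analyte/IS area ratio —
the *response ratio* — cancels matrix effects and extraction losses, and
is linear in concentration.  A calibration line

    r = slope * x + intercept

is fitted to the calibrator series by weighted least squares with
weights 1/x² (relative-error weighting, the standard choice for LC-MS
bioanalysis where noise scales with signal), and subject concentrations
are recovered by inverting the line.

Curve acceptance follows bioanalytical convention: each calibrator is
back-calculated through the fitted line, and the curve is accepted when
at least 75% of levels show |bias| ≤ 15% (≤ 20% at the LLOQ level).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_data import TargetedRun
from .tables import ConcentrationTable

logger = logging.getLogger(__name__)

BIAS_LIMIT = 0.15          # back-calculation bias tolerance
BIAS_LIMIT_LLOQ = 0.20     # relaxed tolerance at the LLOQ level
PASS_FRACTION = 0.75       # fraction of levels that must pass
LLOD_FACTOR = 3.3          # LLOD = 3.3 * sigma / slope


class CalibrationError(ValueError):
    """The calibrator set cannot support a weighted least-squares fit."""


def response_ratio(analyte_area: float, is_area: float) -> float:
    """Analyte / internal-standard peak-area ratio.

    Raises ``ValueError`` for a non-positive IS area: without internal
    standard signal the record is unquantifiable.
    """
    if is_area <= 0:
        raise ValueError("IS area must be positive; record is unquantifiable")
    return analyte_area / is_area


@dataclass
class CalibrationCurve:
    """Weighted least-squares calibration line of one analyte."""

    analyte: str
    slope: float
    intercept: float
    weighting_exponent: float
    weighted_r2: float
    lloq: float = float("nan")
    llod: float = float("nan")
    accepted: bool = False
    level_bias: dict[str, float] = field(default_factory=dict)


def fit_calibration(
    concentrations,
    ratios,
    weighting_exponent: float = 2.0,
    analyte: str = "",
    min_levels: int = 6,
) -> CalibrationCurve:
    """Fit ``ratio = slope·conc + intercept`` by 1/x^e weighted least squares.

    ``weighting_exponent`` 2 gives the 1/x² relative-error weighting; 0
    reduces to ordinary least squares.  Requires at least ``min_levels``
    distinct positive concentrations (1/x² is undefined at zero).
    """
    x = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if x.size != r.size:
        raise ValueError("concentrations and ratios differ in length")
    if np.unique(x).size < min_levels:
        raise CalibrationError(
            f"need >= {min_levels} distinct calibrator levels, got {np.unique(x).size}"
        )
    if weighting_exponent > 0 and np.any(x <= 0):
        raise CalibrationError("1/x^e weighting undefined at non-positive conc")
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate design: all concentrations equal")
    weights = np.ones_like(x) if weighting_exponent == 0 else x ** (-weighting_exponent)
    design = sm.add_constant(x)
    fit = sm.WLS(r, design, weights=weights).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    # weighted R² on the weighted residuals
    resid = r - (slope * x + intercept)
    wmean = np.average(r, weights=weights)
    ss_res = float(np.sum(weights * resid**2))
    ss_tot = float(np.sum(weights * (r - wmean) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        weighting_exponent=weighting_exponent,
        weighted_r2=r2,
    )


def back_calculate(curve: CalibrationCurve, ratio) -> np.ndarray | float:
    """Invert the calibration line: conc = (ratio − intercept) / slope.

    Values below zero are returned as-is (the caller flags them); a
    non-positive slope cannot be inverted.
    """
    if curve.slope <= 0:
        raise ValueError("cannot back-calculate through a non-positive slope")
    ratio = np.asarray(ratio, dtype=float)
    out = (ratio - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


def validate_curve(
    curve: CalibrationCurve, concentrations, ratios
) -> pd.DataFrame:
    """Back-calculation acceptance report; sets ``curve.accepted``.

    Per level: bias = (back-calculated − nominal)/nominal, passing when
    |bias| ≤ 15% (≤ 20% at the lowest, LLOQ-candidate, level).  The
    curve is accepted iff ≥ 75% of levels pass.  A report is always
    returned, listing the failing levels.
    """
    x = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    back = back_calculate(curve, r)
    bias = (back - x) / x
    lowest = x == x.min()
    limit = np.where(lowest, BIAS_LIMIT_LLOQ, BIAS_LIMIT)
    passed = np.abs(bias) <= limit
    curve.accepted = bool(passed.mean() >= PASS_FRACTION)
    curve.level_bias = {f"{xi:g}": float(bi) for xi, bi in zip(x, bias)}
    return pd.DataFrame(
        {
            "nominal_conc": x,
            "back_calculated": back,
            "bias": bias,
            "tolerance": limit,
            "passed": passed,
        }
    )


def detection_limit(sigma: float, slope: float) -> float:
    """LLOD by the 3.3·σ/slope convention."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    return LLOD_FACTOR * sigma / slope


def estimate_limits(
    curve: CalibrationCurve,
    concentrations,
    ratios,
    replicate_qcs: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Estimate (LLOD, LLOQ) from the calibrator residuals.

    LLOQ is the lowest calibrator level whose back-calculation bias is
    within ±20% and, when replicate QC measurements at (or below) that
    level exist, whose replicate CV is ≤ 20%.  LLOD converts the
    response noise at the lowest level to the concentration scale as
    3.3·σ/slope.  When no level qualifies the curve is flagged and LLOQ
    is NaN.

    ``replicate_qcs`` columns: ``nominal_conc``, ``concentration``
    (back-calculated replicate values).
    """
    x = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    order = np.argsort(x)
    x, r = x[order], r[order]
    back = back_calculate(curve, r)
    bias = np.abs((back - x) / x)

    lloq = float("nan")
    for level in np.unique(x):
        sel = x == level
        if np.any(bias[sel] > BIAS_LIMIT_LLOQ):
            continue
        if replicate_qcs is not None:
            near = replicate_qcs[replicate_qcs["nominal_conc"] <= level * 1.0001]
            if len(near) >= 2:
                vals = near["concentration"].to_numpy(dtype=float)
                if vals.mean() > 0 and vals.std(ddof=1) / vals.mean() > 0.20:
                    continue
        lloq = float(level)
        break
    if math.isnan(lloq):
        curve.accepted = False
        logger.warning("%s: no calibrator level qualifies as LLOQ", curve.analyte)

    lowest = x == x.min()
    resid = r - (curve.slope * x + curve.intercept)
    if lowest.sum() >= 2:
        sigma = float(resid[lowest].std(ddof=1))
    else:
        sigma = float(np.abs(resid[lowest]).max())
    llod = detection_limit(sigma, curve.slope)
    curve.lloq, curve.llod = lloq, llod
    return llod, lloq


def calibrate_run(
    run: TargetedRun, weighting_exponent: float = 2.0
) -> dict[str, CalibrationCurve]:
    """Fit, validate and limit-estimate one calibration curve per analyte."""
    curves: dict[str, CalibrationCurve] = {}
    rec = run.records
    for analyte in rec["analyte"].unique():
        cal = rec[(rec["analyte"] == analyte) & (rec["record_type"] == "calibrator")]
        x = cal["nominal_conc"].to_numpy(dtype=float)
        r = (cal["analyte_area"] / cal["is_area"]).to_numpy(dtype=float)
        curve = fit_calibration(x, r, weighting_exponent, analyte=analyte)
        validate_curve(curve, x, r)
        qc = rec[(rec["analyte"] == analyte) & (rec["record_type"] == "qc")]
        reps = None
        if len(qc):
            reps = pd.DataFrame(
                {
                    "nominal_conc": qc["nominal_conc"].to_numpy(dtype=float),
                    "concentration": back_calculate(
                        curve,
                        (qc["analyte_area"] / qc["is_area"]).to_numpy(dtype=float),
                    ),
                }
            )
        estimate_limits(curve, x, r, reps)
        curves[analyte] = curve
    return curves


def quantify(
    run: TargetedRun,
    curves: dict[str, CalibrationCurve],
    dilution_factor: float = 1.0,
) -> ConcentrationTable:
    """Back-calculate subject concentrations through accepted curves.

    Cells quantified below the curve's LLOQ are flagged (``below_lloq``)
    but retained numerically, so the downstream classifier sees the full
    distribution.  Records with missing/non-positive IS area become
    missing cells.  ``dilution_factor`` rescales to the pre-dilution
    plasma concentration (1 = report as measured).
    """
    rec = run.records
    subjects = rec[rec["record_type"] == "subject"]
    sample_ids = list(dict.fromkeys(subjects["sample_id"]))
    analytes = [a for a in rec["analyte"].unique() if a in curves]
    for a in analytes:
        if not curves[a].accepted:
            raise CalibrationError(f"curve for {a} was not accepted")
    conc = pd.DataFrame(np.nan, index=pd.Index(sample_ids), columns=analytes)
    flag = pd.DataFrame(False, index=pd.Index(sample_ids), columns=analytes)
    for a in analytes:
        curve = curves[a]
        sub = subjects[subjects["analyte"] == a]
        for _, row in sub.iterrows():
            if not row["is_area"] > 0:
                logger.warning(
                    "%s / %s: missing IS signal, cell left missing",
                    row["sample_id"], a,
                )
                continue
            ratio = response_ratio(row["analyte_area"], row["is_area"])
            value = back_calculate(curve, ratio) * dilution_factor
            conc.loc[row["sample_id"], a] = value
            if not math.isnan(curve.lloq) and value < curve.lloq:
                flag.loc[row["sample_id"], a] = True
    meta = run.metadata.loc[conc.index] if len(run.metadata) else run.metadata
    return ConcentrationTable(conc, meta, flag)


def curves_report(curves: dict[str, CalibrationCurve]) -> pd.DataFrame:
    """One-row-per-analyte summary of fitted curves (TSV-friendly)."""
    rows = []
    for a, c in curves.items():
        rows.append(
            {
                "analyte": a,
                "slope": c.slope,
                "intercept": c.intercept,
                "weighting_exponent": c.weighting_exponent,
                "weighted_r2": c.weighted_r2,
                "lloq": c.lloq,
                "llod": c.llod,
                "accepted": c.accepted,
            }
        )
    return pd.DataFrame(rows)
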