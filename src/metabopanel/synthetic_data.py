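"""Synthetic cohorts with the statistical structure of plasma LC-MS studies.

Three generators mirror the three phases of a biomarker study:

* :func:`generate_untargeted_cohort` — an aligned untargeted feature table
  (injections × features) for a case/control cohort, with pooled-QC
  injections interleaved in the run sequence, injection-order signal
  drift, batch offsets, heteroscedastic multiplicative noise,
  below-detection censoring, and a subset of features carrying a planted
  case/control log2 fold-change.
* :func:`generate_targeted_run` — a targeted (MRM-style) run: per-analyte
  calibrator series, QC levels and subject samples, each record holding
  an analyte peak area and a stable-isotope-labelled internal-standard
  (SIL-IS) peak area.  True subject concentrations are retained as
  hidden ground truth for recovery tests.
* :func:`generate_nac_cohort` — absolute concentrations of the
  four-metabolite panel for a neoadjuvant-chemotherapy cohort with
  breast-cancer subtype and pCR/non-pCR labels, with a standardized
  effect planted only in chosen marker × subtype cells.

Intensities are lognormal throughout: multiplicative noise, drift and
fold-changes then compose additively on the log scale, which is what the
downstream log-based statistics assume.  All outputs are bit-reproducible
per (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import METADATA_COLUMNS, ConcentrationTable, FeatureTable

PANEL_METABOLITES = ["inosine", "uridine", "phenylalanine", "threonine"]
NAC_SUBTYPES = ["TNBC", "HR+/HER2-", "HER2+"]

DRIFT_SHAPES = {"none", "linear", "exponential_decay", "smooth_random"}


class SpecValidationError(ValueError):
    """A generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# untargeted cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Design of a synthetic untargeted case/control cohort.

    Defaults follow the exploratory design of a plasma discovery study:
    200 cases vs 100 controls, 479 aligned ESI+ features, one pooled QC
    after every 10 subject injections (plus one before and one after the
    sequence).

    Parameters
    ----------
    planted_log2fc
        log2 fold-change (case vs control) carried by each planted feature.
    base_log_mean
        Natural-log intensity scale of a typical feature.
    cv_noise
        Coefficient of variation of the multiplicative lognormal noise.
    drift_amplitude
        Maximum relative intensity change over the injection sequence.
    batch_sd
        SD of the per-batch multiplicative offset, on the log scale.
    missing_rate
        Per-feature probability of below-detection censoring; the lowest
        intensities of each feature are the ones censored.
    """

    n_case: int = 200
    n_control: int = 100
    n_features: int = 479
    n_planted: int = 10
    planted_log2fc: float = 1.0
    base_log_mean: float = 11.5
    cv_noise: float = 0.15
    drift_amplitude: float = 0.2
    drift_shape: str = "smooth_random"
    n_batches: int = 1
    batch_sd: float = 0.0
    qc_every: int = 10
    missing_rate: float = 0.0
    #: spread of per-feature baseline abundances on the natural-log scale.
    #: Squared-weight importance on L2-normalized intensities is abundance-
    #: weighted, so the planted-feature recovery this generator supports
    #: assumes the moderate dynamic range of an identification-filtered
    #: feature table; see the methods note.
    feature_log_sd: float = 0.5

    def __post_init__(self) -> None:
        counts = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_features": self.n_features,
            "n_planted": self.n_planted,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if int(v) != v or v < 0:
                raise SpecValidationError(f"{name} must be a non-negative integer")
        if self.n_batches < 1:
            raise SpecValidationError("n_batches must be >= 1")
        if self.n_planted > self.n_features:
            raise SpecValidationError("n_planted cannot exceed n_features")
        for name in ("cv_noise", "drift_amplitude", "batch_sd", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SpecValidationError(f"{name} must lie in [0, 1)")
        if self.qc_every < 1:
            raise SpecValidationError("qc_every must be >= 1")
        if self.drift_shape not in DRIFT_SHAPES:
            raise SpecValidationError(f"unknown drift_shape {self.drift_shape!r}")


def _drift_profile(shape: str, length: int, amplitude: float, rng) -> np.ndarray:
    """Shared per-injection drift factor g(t) for one batch, g(1) ≈ 1."""
    t = np.arange(length, dtype=float)
    if length <= 1 or amplitude == 0 or shape == "none":
        return np.ones(length)
    u = t / (length - 1)
    if shape == "linear":
        return 1.0 - amplitude * u
    if shape == "exponential_decay":
        # decays most of the way to (1 - amplitude) by the end of the run
        return (1.0 - amplitude) + amplitude * np.exp(-3.0 * u)
    # smooth_random: low-order random Fourier curve scaled to the amplitude
    coeffs = rng.normal(size=3)
    curve = np.zeros(length)
    for k, c in enumerate(coeffs, start=1):
        curve += c * np.sin(np.pi * k * u + rng.uniform(0, 2 * np.pi))
    peak = np.max(np.abs(curve))
    if peak == 0:
        return np.ones(length)
    curve = curve / peak * amplitude
    return 1.0 + curve - curve[0]  # anchor g(1)=1


def _cv_to_log_sd(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def generate_untargeted_cohort(
    spec: CohortSpec, seed: int
) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate an untargeted feature table for one ion mode.

    Returns the :class:`FeatureTable` (QC injections interleaved in
    acquisition order) and its sample metadata.  Planted feature ids are
    available as ``table.planted_features``.
    """
    rng = np.random.default_rng(seed)
    n_sub = spec.n_case + spec.n_control
    feature_ids = [f"F{j + 1:04d}" for j in range(spec.n_features)]

    # per-feature baseline (log scale) and drift sensitivity
    mu = rng.normal(spec.base_log_mean, spec.feature_log_sd, size=spec.n_features)
    sensitivity = rng.uniform(0.5, 1.5, size=spec.n_features)
    planted_idx = np.sort(
        rng.choice(spec.n_features, size=spec.n_planted, replace=False)
    )
    planted = [feature_ids[j] for j in planted_idx]

    groups = np.array(["case"] * spec.n_case + ["control"] * spec.n_control)
    # randomize acquisition order of subjects so drift is not confounded
    # with group
    order_perm = rng.permutation(n_sub)
    groups = groups[order_perm]
    subject_ids = np.array([f"S{i + 1:04d}" for i in range(n_sub)])[order_perm]

    # subject true log-signal: baseline + half the planted effect per arm
    effect = spec.planted_log2fc * math.log(2.0)
    log_true = np.tile(mu, (n_sub, 1))
    case_mask = groups == "case"
    log_true[np.ix_(case_mask, planted_idx)] += effect / 2.0
    log_true[np.ix_(~case_mask, planted_idx)] -= effect / 2.0
    # pooled QC = mean of subject true signals on the natural scale
    qc_log_true = np.log(np.exp(log_true).mean(axis=0))

    # acquisition sequence: QC before, after, and every qc_every subjects
    seq_roles: list[str] = []
    seq_subject: list[int] = []  # row index into log_true, -1 for QC
    n_qc = 0

    def push_qc() -> None:
        nonlocal n_qc
        n_qc += 1
        seq_roles.append("qc")
        seq_subject.append(-1)

    push_qc()
    for i in range(n_sub):
        seq_roles.append("subject")
        seq_subject.append(i)
        if (i + 1) % spec.qc_every == 0 and i + 1 < n_sub:
            push_qc()
    push_qc()
    total = len(seq_roles)

    # contiguous batches of near-equal length
    batch_edges = np.linspace(0, total, spec.n_batches + 1).astype(int)
    batch_of = np.empty(total, dtype=int)
    inj_order = np.empty(total, dtype=int)
    drift = np.empty(total)
    for b in range(spec.n_batches):
        lo, hi = batch_edges[b], batch_edges[b + 1]
        batch_of[lo:hi] = b
        inj_order[lo:hi] = np.arange(1, hi - lo + 1)
        drift[lo:hi] = _drift_profile(
            spec.drift_shape, hi - lo, spec.drift_amplitude, rng
        )
    batch_log_offset = (
        rng.normal(0.0, spec.batch_sd, size=spec.n_batches)
        if spec.batch_sd > 0
        else np.zeros(spec.n_batches)
    )

    sd_log = _cv_to_log_sd(spec.cv_noise)
    log_rows = np.empty((total, spec.n_features))
    for t in range(total):
        base = qc_log_true if seq_subject[t] < 0 else log_true[seq_subject[t]]
        log_rows[t] = base + batch_log_offset[batch_of[t]]
    noise = rng.normal(0.0, sd_log, size=log_rows.shape) if sd_log > 0 else 0.0
    values = np.exp(log_rows + noise)
    # drift is shared across features up to a per-feature sensitivity
    values *= drift[:, None] ** sensitivity[None, :]

    if spec.missing_rate > 0:
        thresh = np.quantile(values, spec.missing_rate, axis=0)
        values = np.where(values < thresh[None, :], np.nan, values)

    qc_counter = 0
    ids, roles, grp = [], [], []
    for t in range(total):
        if seq_subject[t] < 0:
            qc_counter += 1
            ids.append(f"QC{qc_counter:03d}")
            roles.append("qc")
            grp.append("NA")
        else:
            ids.append(subject_ids[seq_subject[t]])
            roles.append("subject")
            grp.append(groups[seq_subject[t]])

    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "role": roles,
            "group": grp,
            "cohort": "exploratory",
            "subtype": "NA",
            "response": "NA",
            "injection_order": inj_order,
            "batch": [f"B{b + 1}" for b in batch_of],
        },
        index=ids,
    )[METADATA_COLUMNS]
    meta.index.name = None
    intens = pd.DataFrame(values, index=ids, columns=feature_ids)
    table = FeatureTable(intens, meta, planted_features=planted)
    return table, meta


# ---------------------------------------------------------------------------
# targeted runs
# ---------------------------------------------------------------------------


@dataclass
class AnalyteSpec:
    """True calibration line and concentration range for one analyte."""

    name: str
    slope: float  # response ratio per (ng/mL)
    intercept: float  # response ratio
    calibrator_levels: tuple[float, ...]  # 13 strictly increasing, ng/mL
    lloq_nominal: float  # ng/mL

    def __post_init__(self) -> None:
        levels = np.asarray(self.calibrator_levels, dtype=float)
        if len(levels) != 13:
            raise SpecValidationError(
                f"{self.name}: expected 13 calibrator levels, got {len(levels)}"
            )
        if not np.all(np.diff(levels) > 0):
            raise SpecValidationError(
                f"{self.name}: calibrator levels must be strictly increasing"
            )


def _geometric_levels(center: float, n: int = 13, step: float = 2.0) -> tuple:
    lo = center / step ** ((n - 1) / 2)
    return tuple(lo * step**k for k in range(n))


def _default_analytes() -> list[AnalyteSpec]:
    # geometric-mean plasma levels roughly matching the SIL-IS spike scale
    centers = {
        "inosine": 5.0,
        "uridine": 250.0,
        "phenylalanine": 500.0,
        "threonine": 500.0,
    }
    out = []
    for name, c in centers.items():
        levels = _geometric_levels(c)
        out.append(
            AnalyteSpec(
                name=name,
                slope=1.0 / c,
                intercept=0.0,
                calibrator_levels=levels,
                lloq_nominal=levels[0],
            )
        )
    return out


def _default_qc_levels(analytes: list[AnalyteSpec]) -> dict[str, tuple]:
    # low / low-medium / high-medium / high relative to the calibration range
    out = {}
    for a in analytes:
        lo, hi = a.calibrator_levels[0], a.calibrator_levels[-1]
        span = math.log(hi / lo)
        out[a.name] = tuple(
            lo * math.exp(f * span) for f in (0.15, 0.4, 0.65, 0.85)
        )
    return out


def _default_subject_conc() -> dict[str, dict[str, tuple[float, float]]]:
    # (log_mean, log_sd) per group; cases: nucleosides down, amino acids up.
    # Shift magnitudes chosen so the four-marker concentration classifier
    # reaches the ~90% accuracy regime reported for targeted nucleoside/
    # amino-acid panels in early breast-cancer detection.
    gm = {"inosine": 5.0, "uridine": 250.0, "phenylalanine": 500.0, "threonine": 500.0}
    shift = {
        "inosine": -0.8,
        "uridine": -0.6,
        "phenylalanine": 0.5,
        "threonine": 0.45,
    }
    log_sd = 0.4
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for name, c in gm.items():
        out[name] = {
            "control": (math.log(c), log_sd),
            "case": (math.log(c) + shift[name], log_sd),
        }
    return out


@dataclass
class TargetedPanelSpec:
    """Design of a synthetic targeted (MRM-style) quantification run.

    Defaults emulate a validation-phase training cohort: four panel
    analytes, 13 calibrators each, QC samples at four concentration
    levels, 283 cases and 140 controls.
    """

    analytes: list[AnalyteSpec] = field(default_factory=_default_analytes)
    qc_levels: dict[str, tuple] | None = None
    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"case": 283, "control": 140}
    )
    subject_conc: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_subject_conc
    )
    ratio_cv: float = 0.05
    is_area_nominal: float = 1e5
    is_area_cv: float = 0.03
    n_qc_replicates: int = 3
    cohort: str = "training"

    def __post_init__(self) -> None:
        if self.qc_levels is None:
            self.qc_levels = _default_qc_levels(self.analytes)
        for a in self.analytes:
            qcs = np.asarray(self.qc_levels[a.name], dtype=float)
            if len(qcs) != 4 or not np.all(np.diff(qcs) > 0):
                raise SpecValidationError(
                    f"{a.name}: exactly 4 QC levels, ordered low < low-medium"
                    " < high-medium < high"
                )
        for name, n in self.n_subjects_per_group.items():
            if n < 0:
                raise SpecValidationError(f"group {name!r} size must be >= 0")
        if not 0 <= self.ratio_cv < 1:
            raise SpecValidationError("ratio_cv must lie in [0, 1)")


QC_LEVEL_LABELS = ["low", "low_medium", "high_medium", "high"]

RUN_COLUMNS = [
    "analyte",
    "record_type",
    "level",
    "nominal_conc",
    "analyte_area",
    "is_area",
    "sample_id",
    "group",
]


@dataclass
class TargetedRun:
    """Peak-area records of one targeted run, plus hidden ground truth."""

    records: pd.DataFrame  # columns RUN_COLUMNS
    true_concentrations: pd.DataFrame  # subjects × analytes, ng/mL
    metadata: pd.DataFrame  # subject sample sheet

    def write(self, records_path) -> None:
        self.records.to_csv(records_path, sep="\t", index=False)

    @classmethod
    def read(cls, records_path) -> "TargetedRun":
        rec = pd.read_csv(records_path, sep="\t")
        missing = [c for c in RUN_COLUMNS if c not in rec.columns]
        if missing:
            raise ValueError(f"targeted run missing column(s): {', '.join(missing)}")
        subjects = rec.loc[rec["record_type"] == "subject", "sample_id"].unique()
        empty = pd.DataFrame(index=pd.Index(subjects, name="sample_id"))
        meta = pd.DataFrame(
            {
                "sample_id": subjects,
                "group": [
                    rec.loc[rec["sample_id"] == s, "group"].iloc[0] for s in subjects
                ],
            },
            index=pd.Index(subjects),
        )
        meta.index.name = None
        return cls(rec, empty, meta)


def generate_targeted_run(spec: TargetedPanelSpec, seed: int) -> TargetedRun:
    """Simulate calibrator, QC and subject peak-area records.

    The response ratio of every record is (slope·x + intercept) times a
    multiplicative lognormal error of CV ``ratio_cv``; analyte and IS
    areas are derived from the ratio and a noisy IS area so that common
    detector gain cancels exactly.
    """
    rng = np.random.default_rng(seed)
    sd_ratio = _cv_to_log_sd(spec.ratio_cv)
    sd_is = _cv_to_log_sd(spec.is_area_cv)

    groups_expanded: list[tuple[str, str]] = []
    for grp, n in sorted(spec.n_subjects_per_group.items()):
        for i in range(n):
            groups_expanded.append((f"{spec.cohort}_{grp}_{i + 1:04d}", grp))

    true_conc: dict[str, np.ndarray] = {}
    rows: list[dict] = []
    for a in spec.analytes:
        # calibrators
        for lvl, x in enumerate(a.calibrator_levels, start=1):
            ratio = a.slope * x + a.intercept
            if sd_ratio > 0:
                ratio *= math.exp(rng.normal(0.0, sd_ratio))
            is_area = spec.is_area_nominal * (
                math.exp(rng.normal(0.0, sd_is)) if sd_is > 0 else 1.0
            )
            rows.append(
                {
                    "analyte": a.name,
                    "record_type": "calibrator",
                    "level": str(lvl),
                    "nominal_conc": x,
                    "analyte_area": ratio * is_area,
                    "is_area": is_area,
                    "sample_id": f"cal_{a.name}_{lvl:02d}",
                    "group": "NA",
                }
            )
        # QC levels, replicated
        for label, x in zip(QC_LEVEL_LABELS, spec.qc_levels[a.name]):
            for rep in range(1, spec.n_qc_replicates + 1):
                ratio = a.slope * x + a.intercept
                if sd_ratio > 0:
                    ratio *= math.exp(rng.normal(0.0, sd_ratio))
                is_area = spec.is_area_nominal * (
                    math.exp(rng.normal(0.0, sd_is)) if sd_is > 0 else 1.0
                )
                rows.append(
                    {
                        "analyte": a.name,
                        "record_type": "qc",
                        "level": label,
                        "nominal_conc": x,
                        "analyte_area": ratio * is_area,
                        "is_area": is_area,
                        "sample_id": f"qc_{a.name}_{label}_{rep}",
                        "group": "NA",
                    }
                )
        # subjects
        conc_params = spec.subject_conc[a.name]
        truths = np.empty(len(groups_expanded))
        for i, (sid, grp) in enumerate(groups_expanded):
            log_mean, log_sd = conc_params[grp]
            x = math.exp(rng.normal(log_mean, log_sd))
            truths[i] = x
            ratio = a.slope * x + a.intercept
            if sd_ratio > 0:
                ratio *= math.exp(rng.normal(0.0, sd_ratio))
            is_area = spec.is_area_nominal * (
                math.exp(rng.normal(0.0, sd_is)) if sd_is > 0 else 1.0
            )
            rows.append(
                {
                    "analyte": a.name,
                    "record_type": "subject",
                    "level": "NA",
                    "nominal_conc": np.nan,
                    "analyte_area": ratio * is_area,
                    "is_area": is_area,
                    "sample_id": sid,
                    "group": grp,
                }
            )
        true_conc[a.name] = truths

    records = pd.DataFrame(rows, columns=RUN_COLUMNS)
    sids = [sid for sid, _ in groups_expanded]
    truth = pd.DataFrame(true_conc, index=pd.Index(sids, name="sample_id"))
    truth.index.name = None
    meta = pd.DataFrame(
        {
            "sample_id": sids,
            "role": "subject",
            "group": [g for _, g in groups_expanded],
            "cohort": spec.cohort,
            "subtype": "NA",
            "response": "NA",
            "injection_order": np.arange(1, len(sids) + 1),
            "batch": "B1",
        },
        index=pd.Index(sids),
    )[METADATA_COLUMNS]
    meta.index.name = None
    return TargetedRun(records, truth, meta)


# ---------------------------------------------------------------------------
# NAC cohorts
# ---------------------------------------------------------------------------


@dataclass
class NacCohortSpec:
    """Design of a synthetic neoadjuvant-chemotherapy response cohort.

    ``group_sizes`` maps each breast-cancer subtype to (n_pCR, n_non_pCR);
    the TNBC default (27 vs 25) matches the published response cohort.
    ``effect_d`` is the standardized mean difference on the log
    concentration scale; the pCR group is shifted *down* by ``effect_d``
    standard deviations, and only for ``affected_markers`` within
    ``affected_subtypes``.
    """

    group_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "TNBC": (27, 25),
            "HR+/HER2-": (30, 30),
            "HER2+": (20, 20),
        }
    )
    effect_d: float = 1.0
    affected_markers: tuple[str, ...] = ("inosine",)
    affected_subtypes: tuple[str, ...] = ("TNBC",)
    log_means: dict[str, float] = field(
        default_factory=lambda: {
            "inosine": math.log(5.0),
            "uridine": math.log(250.0),
            "phenylalanine": math.log(500.0),
            "threonine": math.log(500.0),
        }
    )
    log_sd: float = 0.5
    #: pairwise correlation of marker log-concentrations within a subject
    #: (a shared subject-level factor: plasma metabolite levels co-vary).
    #: At 0.5 a log-ratio of two markers has the same variance as a single
    #: marker, so a planted standardized difference d yields the binormal
    #: AUC Φ(d/√2) for markers and two-marker ratios alike.
    marker_correlation: float = 0.5

    def __post_init__(self) -> None:
        for subtype, (a, b) in self.group_sizes.items():
            if a < 0 or b < 0:
                raise SpecValidationError(f"{subtype}: group sizes must be >= 0")
        unknown = set(self.affected_markers) - set(PANEL_METABOLITES)
        if unknown:
            raise SpecValidationError(f"unknown marker(s): {sorted(unknown)}")
        unknown = set(self.affected_subtypes) - set(self.group_sizes)
        if unknown:
            raise SpecValidationError(f"unknown subtype(s): {sorted(unknown)}")
        if self.log_sd <= 0:
            raise SpecValidationError("log_sd must be positive")
        if not 0 <= self.marker_correlation < 1:
            raise SpecValidationError("marker_correlation must lie in [0, 1)")


def generate_nac_cohort(
    spec: NacCohortSpec, seed: int
) -> tuple[ConcentrationTable, pd.DataFrame]:
    """Simulate panel-metabolite concentrations for an NAC cohort."""
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    conc_rows: list[np.ndarray] = []
    markers = PANEL_METABOLITES
    i = 0
    for subtype in spec.group_sizes:
        n_pcr, n_non = spec.group_sizes[subtype]
        for response, n in (("pCR", n_pcr), ("non-pCR", n_non)):
            for _ in range(n):
                i += 1
                rho = spec.marker_correlation
                shared = rng.normal()  # subject-level factor
                vals = np.empty(len(markers))
                for m, marker in enumerate(markers):
                    mean = spec.log_means[marker]
                    if (
                        response == "pCR"
                        and marker in spec.affected_markers
                        and subtype in spec.affected_subtypes
                    ):
                        mean -= spec.effect_d * spec.log_sd
                    z = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.normal()
                    vals[m] = math.exp(mean + spec.log_sd * z)
                conc_rows.append(vals)
                rows.append(
                    {
                        "sample_id": f"NAC{i:04d}",
                        "role": "subject",
                        "group": "case",
                        "cohort": "nac",
                        "subtype": subtype,
                        "response": response,
                        "injection_order": i,
                        "batch": "B1",
                    }
                )
    meta = pd.DataFrame(rows, index=[r["sample_id"] for r in rows])[METADATA_COLUMNS]
    meta.index.name = None
    conc = pd.DataFrame(conc_rows, index=meta.index, columns=markers)
    return ConcentrationTable(conc, meta), meta
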