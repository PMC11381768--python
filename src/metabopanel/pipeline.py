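"""End-to-end orchestration of the three study phases.

Mirrors the design of a plasma biomarker study:

1. **discovery** — untargeted ESI+ and ESI− feature tables are imputed,
   drift-corrected and fed to SVM-based feature selection; candidate
   features from both ion modes are pooled and a minimal panel is chosen
   on the concatenated (per-mode L2-normalized) matrix.
2. **validation** — targeted runs are calibrated (1/x² WLS), subjects
   absolutely quantified, and an SVM on concentrations is trained on the
   training cohort and evaluated on training/test/independent cohorts.
3. **nac** — panel concentrations of a neoadjuvant-chemotherapy cohort
   are tested per marker × subtype (Welch + BH) and the inosine/uridine
   ratio is evaluated as a response predictor per subtype.

Every phase writes JSON/TSV reports with a provenance block (config
hash, seed, package version) and logs per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, drift_correction, evaluation, panel_selection, svm_core
from . import synthetic_data as synth
from . import targeted_quant
from .tables import ConcentrationTable, FeatureTable, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    # simulation design (exploratory cohort)
    "n_case": 200,
    "n_control": 100,
    "features_pos": 479,
    "features_neg": 269,
    "n_planted": 10,
    "planted_log2fc": 1.0,
    "cv_noise": 0.15,
    "drift_amplitude": 0.2,
    "drift_shape": "smooth_random",
    "n_batches": 1,
    "batch_sd": 0.0,
    "qc_every": 10,
    "missing_rate": 0.05,
    # discovery protocol
    "folds": 4,
    "n_iter_importance": 2000,
    "n_iter_topn": 500,
    "max_n": 100,
    "c_discovery": 4.0,
    "tolerance": 0.01,
    "trend_method": "loess_like",
    # validation / targeted phase
    "c_validation": 5.0,
    "weighting_exponent": 2.0,
    "dilution_factor": 1.0,
    "ratio_cv": 0.05,
    # log-transform concentrations before per-sample normalization
    "log_concentrations": False,
    # NAC phase
    "nac_effect_d": 1.0,
    "nac_q": 0.05,
    # input paths (None = look in the output directory of `simulate`)
    "pos_table": None,
    "pos_metadata": None,
    "neg_table": None,
    "neg_metadata": None,
    "targeted_training": None,
    "targeted_test": None,
    "targeted_validation": None,
    "nac_concentrations": None,
    "nac_metadata": None,
}


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file over the defaults; unknown keys are fatal."""
    config = dict(DEFAULT_CONFIG)
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise SchemaError("config file must be a mapping")
    if overrides:
        user.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(user) - set(config)
    if unknown:
        raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    config.update(user)
    return config


def provenance(config: dict, seed: int) -> dict:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "version": __version__,
    }


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(config: dict, seed: int, out_dir: str | Path) -> dict:
    """Generate and write all synthetic inputs for the other phases."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(seed, 7)

    paths: dict[str, str] = {}
    for mode, n_feat, s in (
        ("pos", config["features_pos"], seeds[0]),
        ("neg", config["features_neg"], seeds[1]),
    ):
        spec = synth.CohortSpec(
            n_case=config["n_case"],
            n_control=config["n_control"],
            n_features=n_feat,
            n_planted=config["n_planted"],
            planted_log2fc=config["planted_log2fc"],
            cv_noise=config["cv_noise"],
            drift_amplitude=config["drift_amplitude"],
            drift_shape=config["drift_shape"],
            n_batches=config["n_batches"],
            batch_sd=config["batch_sd"],
            qc_every=config["qc_every"],
            missing_rate=config["missing_rate"],
        )
        table, _ = synth.generate_untargeted_cohort(spec, s)
        ti = out / f"untargeted_{mode}.tsv"
        tm = out / f"untargeted_{mode}_metadata.tsv"
        table.write(ti, tm)
        (out / f"untargeted_{mode}_planted.json").write_text(
            json.dumps(table.planted_features)
        )
        paths[f"{mode}_table"], paths[f"{mode}_metadata"] = str(ti), str(tm)
        logger.info("simulate: %s mode — %d injections × %d features",
                    mode, table.n_samples, table.n_features)

    cohorts = {
        "training": {"case": 283, "control": 140},
        "test": {"case": 150, "control": 126},
        "validation": {"case": 70, "control": 42},
    }
    for (name, sizes), s in zip(cohorts.items(), seeds[2:5]):
        spec = synth.TargetedPanelSpec(
            n_subjects_per_group=sizes, ratio_cv=config["ratio_cv"], cohort=name
        )
        run = synth.generate_targeted_run(spec, s)
        p = out / f"targeted_{name}.tsv"
        run.write(p)
        paths[f"targeted_{name}"] = str(p)
        logger.info("simulate: targeted %s — %d records", name, len(run.records))

    nac_spec = synth.NacCohortSpec(effect_d=config["nac_effect_d"])
    nac, _ = synth.generate_nac_cohort(nac_spec, seeds[5])
    pc, pm = out / "nac_concentrations.tsv", out / "nac_metadata.tsv"
    nac.write(pc, pm)
    paths["nac_concentrations"], paths["nac_metadata"] = str(pc), str(pm)
    logger.info("simulate: NAC cohort — %d subjects", len(nac.concentrations))

    report = {"provenance": provenance(config, seed), "paths": paths}
    _write_json(report, out / "simulate_report.json")
    return report


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------


def _discover_mode(
    table: FeatureTable, config: dict, seed: int, out: Path, mode: str
) -> dict:
    """Impute, drift-correct and rank one ion mode; return per-mode state."""
    n_in = table.n_samples
    imputed = drift_correction.impute_missing(table)
    corrected, qc_report = drift_correction.correct_table(
        imputed, method=config["trend_method"], seed=seed
    )
    qc_report.to_csv(out / f"qc_report_{mode}.tsv", sep="\t", index=False)
    subjects = corrected.subjects()
    logger.info(
        "discovery[%s]: %d injections in = %d subjects + %d QCs out",
        mode, n_in, subjects.n_samples, n_in - subjects.n_samples,
    )
    X = subjects.intensities.to_numpy(dtype=float)
    y = subjects.labels()
    cv = panel_selection.repeated_cv(
        X, y,
        folds=config["folds"],
        n_iter=config["n_iter_importance"],
        c=config["c_discovery"],
        seed=seed,
    )
    ranking = panel_selection.rank_features(cv)
    feature_ids = subjects.feature_ids
    pd.DataFrame(
        {"feature_id": feature_ids, "importance": cv.importance}
    ).to_csv(out / f"importance_{mode}.tsv", sep="\t", index=False)
    return {
        "X": X,
        "y": y,
        "cv": cv,
        "ranking": ranking,
        "feature_ids": feature_ids,
        "planted": list(table.planted_features),
    }


def run_discovery(config: dict, seed: int, out_dir: str | Path) -> dict:
    """Discovery phase: drift correction, importance, top-N, panel."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(seed, 4)

    modes: dict[str, dict] = {}
    for i, mode in enumerate(("pos", "neg")):
        t_path = config[f"{mode}_table"] or out / f"untargeted_{mode}.tsv"
        m_path = config[f"{mode}_metadata"] or out / f"untargeted_{mode}_metadata.tsv"
        if not Path(t_path).exists():
            if mode == "neg":
                continue  # single-mode runs are allowed
            raise SchemaError(f"missing input table: {t_path}")
        table = FeatureTable.read(t_path, m_path)
        modes[mode] = _discover_mode(table, config, seeds[i], out, mode)

    # per-mode candidate selection, then pooling on the concatenated
    # (per-mode-normalized) candidate matrix
    pooled_X, pooled_ids, y = [], [], None
    per_mode_summary = {}
    for mode, st in modes.items():
        max_n = min(config["max_n"], len(st["feature_ids"]))
        curve = panel_selection.topn_accuracy_curve(
            st["X"], st["y"], st["ranking"],
            max_n=max_n,
            folds=config["folds"],
            n_iter=config["n_iter_topn"],
            c=config["c_discovery"],
            seed=seeds[2],
        )
        pd.DataFrame(
            {
                "n": curve.n,
                "mean_accuracy": curve.mean_accuracy,
                "ci_lower": curve.ci_lower,
                "ci_upper": curve.ci_upper,
            }
        ).to_csv(out / f"topn_curve_{mode}.tsv", sep="\t", index=False)
        candidates = panel_selection.select_panel(
            curve, st["ranking"], tolerance=config["tolerance"]
        )
        per_mode_summary[mode] = {
            "cv": st["cv"].summary(),
            "n_candidates": len(candidates),
            "candidates": [st["feature_ids"][int(j)] for j in candidates],
        }
        Xn = svm_core.l2_normalize(st["X"])  # per-mode row normalization
        pooled_X.append(Xn[:, np.asarray(candidates, dtype=int)])
        pooled_ids.extend(
            f"{mode}:{st['feature_ids'][int(j)]}" for j in candidates
        )
        y = st["y"]

    Xp = np.concatenate(pooled_X, axis=1)
    logger.info("discovery: pooled %d candidate features", Xp.shape[1])
    cv_pool = panel_selection.repeated_cv(
        Xp, y,
        folds=config["folds"],
        n_iter=config["n_iter_topn"],
        c=config["c_discovery"],
        seed=seeds[3],
        normalize=False,
    )
    pool_ranking = panel_selection.rank_features(cv_pool)
    pool_curve = panel_selection.topn_accuracy_curve(
        Xp, y, pool_ranking,
        max_n=Xp.shape[1],
        folds=config["folds"],
        n_iter=config["n_iter_topn"],
        c=config["c_discovery"],
        seed=seeds[3],
        normalize=False,
    )
    panel_idx = panel_selection.select_panel(
        pool_curve, pool_ranking, tolerance=config["tolerance"]
    )
    panel = [pooled_ids[int(j)] for j in panel_idx]

    report = {
        "provenance": provenance(config, seed),
        "modes": per_mode_summary,
        "pooled_cv": cv_pool.summary(),
        "panel": panel,
    }
    _write_json(report, out / "discovery_report.json")
    (out / "panel.tsv").write_text("feature_id\n" + "\n".join(panel) + "\n")
    return report


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _labels_from_meta(meta: pd.DataFrame) -> np.ndarray:
    return np.where(meta["group"].to_numpy() == "case", 1, -1)


def _conc_matrix(conc_df: pd.DataFrame, config: dict) -> np.ndarray:
    """Concentrations as a float matrix, optionally log-transformed.

    Back-calculated concentrations can be non-positive near the LLOD;
    under the log option they are floored at 1/10 of the smallest
    positive value of their analyte.
    """
    X = conc_df.to_numpy(dtype=float)
    if config["log_concentrations"]:
        X = X.copy()
        for j in range(X.shape[1]):
            col = X[:, j]
            floor = col[col > 0].min() / 10.0
            X[:, j] = np.log(np.maximum(col, floor))
    return X


def run_validation(config: dict, seed: int, out_dir: str | Path) -> dict:
    """Targeted phase: calibrate, quantify, train (c=c_validation), evaluate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohorts = {}
    for name in ("training", "test", "validation"):
        p = config[f"targeted_{name}"] or out / f"targeted_{name}.tsv"
        if not Path(p).exists():
            raise SchemaError(f"missing targeted run: {p}")
        run = synth.TargetedRun.read(p)
        # calibration is refitted per cohort file (per analytical batch)
        curves = targeted_quant.calibrate_run(run, config["weighting_exponent"])
        conc = targeted_quant.quantify(run, curves, config["dilution_factor"])
        targeted_quant.curves_report(curves).to_csv(
            out / f"curves_{name}.tsv", sep="\t", index=False
        )
        conc.concentrations.to_csv(
            out / f"concentrations_{name}.tsv", sep="\t", index_label="sample_id"
        )
        cohorts[name] = conc
        logger.info("validation: %s — %d subjects quantified", name,
                    len(conc.concentrations))

    train = cohorts["training"]
    analytes = train.analytes
    Xtr = svm_core.l2_normalize(_conc_matrix(train.concentrations, config))
    ytr = _labels_from_meta(train.metadata)
    model = svm_core.train_linear_svm(
        Xtr, ytr, c=config["c_validation"], feature_ids=analytes
    )
    (out / "validation_model.json").write_text(model.to_json() + "\n")

    results = {}
    for name, conc in cohorts.items():
        X = svm_core.l2_normalize(_conc_matrix(conc.concentrations[analytes], config))
        y = _labels_from_meta(conc.metadata)
        scores = svm_core.decision_values(model, X)
        pred = svm_core.predict(model, X)
        cm = evaluation.confusion_metrics(y, pred)
        roc = evaluation.roc_auc(scores, y)
        pr = evaluation.pr_curve(scores, y)
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
            out / f"roc_{name}.tsv", sep="\t", index=False
        )
        pd.DataFrame({"recall": pr.recall, "precision": pr.precision}).to_csv(
            out / f"pr_{name}.tsv", sep="\t", index=False
        )
        results[name] = {
            "n": int(len(y)),
            "accuracy": cm.accuracy,
            "sensitivity": cm.sensitivity,
            "specificity": cm.specificity,
            "auc": roc.auc,
            "average_precision": pr.average_precision,
        }
    report = {"provenance": provenance(config, seed), "cohorts": results}
    _write_json(report, out / "validation_report.json")
    return report


# ---------------------------------------------------------------------------
# NAC
# ---------------------------------------------------------------------------


def run_nac(config: dict, seed: int, out_dir: str | Path) -> dict:
    """NAC phase: per marker × subtype tests (BH family) + ratio marker."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pc = config["nac_concentrations"] or out / "nac_concentrations.tsv"
    pm = config["nac_metadata"] or out / "nac_metadata.tsv"
    if not Path(pc).exists():
        raise SchemaError(f"missing NAC concentration table: {pc}")
    conc = ConcentrationTable.read(pc, pm)
    meta = conc.metadata
    if "subtype" not in meta.columns or meta["subtype"].isna().all():
        raise SchemaError("NAC metadata must carry subtype labels")

    cells = []
    for marker in conc.analytes:
        for subtype, sub in meta.groupby("subtype", sort=False):
            vals = np.log(conc.concentrations.loc[sub.index, marker].to_numpy())
            outcomes = sub["response"]
            if len(set(outcomes)) < 2:
                continue
            t, p = evaluation.group_difference_test(vals, outcomes)
            y = np.where(outcomes == "non-pCR", 1, -1)
            auc = evaluation.roc_auc(
                conc.concentrations.loc[sub.index, marker].to_numpy(), y
            ).auc
            cells.append(
                {"marker": marker, "subtype": subtype, "t": t, "p": p, "auc": auc}
            )
    cells_df = pd.DataFrame(cells)
    cells_df["p_adjusted"] = evaluation.bh_adjust(cells_df["p"].to_numpy())
    cells_df["significant"] = cells_df["p_adjusted"] <= config["nac_q"]
    cells_df.to_csv(out / "nac_markers.tsv", sep="\t", index=False)

    ratio = evaluation.ratio_marker_analysis(conc, "inosine", "uridine")
    ratio.to_csv(out / "nac_ratio_inosine_uridine.tsv", sep="\t", index=False)

    report = {
        "provenance": provenance(config, seed),
        "markers": cells_df.to_dict(orient="records"),
        "ratio_inosine_uridine": ratio.to_dict(orient="records"),
    }
    _write_json(report, out / "nac_report.json")
    return report


def run_all(config: dict, seed: int, out_dir: str | Path) -> dict:
    """Simulate a study, then run discovery, validation and NAC phases."""
    run_simulate(config, seed, out_dir)
    return {
        "discovery": run_discovery(config, seed, out_dir),
        "validation": run_validation(config, seed, out_dir),
        "nac": run_nac(config, seed, out_dir),
    }
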