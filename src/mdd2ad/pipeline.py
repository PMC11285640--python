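"""End-to-end orchestration: simulate/ingest → cohort → split → weights → models → reports.

All artifacts are delimited text or JSON; every writer leaves a sidecar
provenance record and the run manifest stores the config hash, derived
stage seeds and a content hash per artifact, so two runs under the same
master seed produce identical manifests (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .causal_weights import (
    build_panel,
    compute_iptw,
    fit_exposure_models,
    fit_msm,
    predict_msm,
    rank_msm_features,
)
from .cohort_builder import (
    FEATURE_COLUMNS,
    build_cohort_table,
    build_outcome,
    descriptive_table,
    encode_features,
    render_descriptive_table,
)
from .config import RunConfig, config_hash, save_config
from .ensemble_ipm import fit_ipm, predict_ipm, split_cohort
from .evaluation import auc_with_ci, compare_models, confusion_and_metrics
from .neural_model import predict_mlp, rank_mlp_features
from .sensitivity import run_sensitivity
from .synthetic_claims import Claim, PatientRecord, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "ingest_external", "write_cohort_files", "read_cohort_files"]

CLAIMS_COLUMNS = ["patient_id", "year", "code_system", "code", "utilization_days"]
PATIENT_COLUMNS = ["patient_id", "age_group", "gender", "race", "rural_urban", "hpsa"]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _provenance(path: Path, seed: int, cfg_hash: str) -> None:
    sidecar = path.with_suffix(path.suffix + ".prov.json")
    sidecar.write_text(
        json.dumps(
            {"seed": seed, "config_hash": cfg_hash, "generator_version": __version__},
            sort_keys=True,
        )
    )


def write_cohort_files(
    records: list[PatientRecord], outdir: str | Path, seed: int = 0, cfg_hash: str = ""
) -> tuple[Path, Path]:
    """Serialize records as a long-format claims file and a flat patient file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    claims_rows = [
        (r.patient_id, c.year, c.code_system, c.code, c.utilization_days)
        for r in records
        for c in r.claims
    ]
    claims_path = outdir / "claims.csv"
    patients_path = outdir / "patients.csv"
    pd.DataFrame(claims_rows, columns=CLAIMS_COLUMNS).to_csv(claims_path, index=False)
    pd.DataFrame(
        [
            (r.patient_id, r.age_group, r.gender, r.race, r.rural_urban, r.hpsa)
            for r in records
        ],
        columns=PATIENT_COLUMNS,
    ).to_csv(patients_path, index=False)
    for p in (claims_path, patients_path):
        _provenance(p, seed, cfg_hash)
    return claims_path, patients_path


def ingest_external(
    claims_file: str | Path, patients_file: str | Path
) -> tuple[list[PatientRecord], dict]:
    """Read the documented claims/patients schemas into patient records.

    Rows failing validation (non-integer year, unknown code system,
    negative utilization, claims for unknown patients) are rejected and
    counted with reasons; an empty claims file is an error.
    """
    claims = pd.read_csv(claims_file, dtype=str)
    patients = pd.read_csv(patients_file, dtype=str)
    for col in CLAIMS_COLUMNS:
        if col not in claims.columns:
            raise ValueError(f"claims file is missing mandatory column {col!r}")
    for col in PATIENT_COLUMNS:
        if col not in patients.columns:
            raise ValueError(f"patients file is missing mandatory column {col!r}")
    if len(claims) == 0:
        raise ValueError("claims file contains no rows")

    rejects: dict[str, int] = {}

    def _reject(reason: str):
        rejects[reason] = rejects.get(reason, 0) + 1

    records: dict[str, PatientRecord] = {}
    for _, row in patients.iterrows():
        records[row["patient_id"]] = PatientRecord(
            patient_id=row["patient_id"],
            age_group=row["age_group"],
            gender=row["gender"],
            race=row["race"],
            rural_urban=row["rural_urban"],
            hpsa=row["hpsa"],
            claims=[],
        )
    for _, row in claims.iterrows():
        pid = row["patient_id"]
        if pid not in records:
            _reject("unknown patient_id")
            continue
        try:
            year = int(row["year"])
        except (TypeError, ValueError):
            _reject("malformed year")
            continue
        if row["code_system"] not in ("ICD9", "ICD10"):
            _reject("unknown code system")
            continue
        try:
            util = int(row["utilization_days"])
        except (TypeError, ValueError):
            _reject("malformed utilization_days")
            continue
        if util < 0:
            _reject("negative utilization_days")
            continue
        records[pid].claims.append(Claim(year, row["code_system"], row["code"], util))
    for rec in records.values():
        rec.claims.sort(key=lambda c: c.year)
    if rejects:
        logger.warning("ingest rejected rows: %s", rejects)
    return list(records.values()), rejects


def read_cohort_files(claims_file, patients_file) -> list[PatientRecord]:
    records, _ = ingest_external(claims_file, patients_file)
    return records


def _round_report(rep: dict, nd: int) -> dict:
    def r(v):
        if isinstance(v, float):
            return round(v, nd)
        if isinstance(v, dict):
            return {k: r(x) for k, x in v.items()}
        if isinstance(v, list):
            return [r(x) for x in v]
        return v

    return {k: r(v) for k, v in rep.items()}


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    records: list[PatientRecord] | None = None,
    make_plots: bool = False,
) -> dict:
    """Execute the full study pipeline and write all artifacts.

    Stage order: simulate (or use supplied records) → cohort table →
    stratified split → exposure panel, stabilized weights and the
    weighted marginal structural model → perceptron → stacked ensemble →
    evaluation panel → sensitivity protocol (optional).  Returns the
    manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    manifest: dict = {
        "config_hash": cfg_hash,
        "version": __version__,
        "stages": {},
        "artifacts": {},
    }
    save_config(config, outdir / "config.yaml")

    def _stage(name: str):
        seed = config.stage_seed(name)
        manifest["stages"][name] = {"seed": seed}
        logger.info("stage %s (seed %d)", name, seed)
        return seed, time.perf_counter()

    def _done(name: str, t0: float, n: int):
        manifest["stages"][name]["wall_seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name]["n_records"] = n

    # --- simulate / ingest ---
    seed, t0 = _stage("simulate")
    if records is None:
        sim_cfg = config.simulation.replace(seed=seed)
        records = simulate_cohort(sim_cfg)
    write_cohort_files(records, outdir, seed, cfg_hash)
    _done("simulate", t0, len(records))

    # --- cohort construction ---
    _, t0 = _stage("cohort")
    labeled, summary = build_outcome(records)
    cohort = build_cohort_table(labeled)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    desc = descriptive_table(cohort)
    desc.to_csv(outdir / "descriptives.csv", index=False)
    (outdir / "descriptives.txt").write_text(render_descriptive_table(desc) + "\n")
    manifest["stages"]["cohort"]["outcome_summary"] = vars(summary)
    _done("cohort", t0, len(cohort))

    # --- split ---
    split_seed, t0 = _stage("split")
    train, test = split_cohort(cohort, config.train_fraction, seed=split_seed)
    y_tr = train["outcome"].to_numpy(int)
    y_te = test["outcome"].to_numpy(int)
    _done("split", t0, len(train))

    # --- stabilized weights + MSM ---
    _, t0 = _stage("weights")
    train_records = [r for r, _ in labeled if r.patient_id in set(train["patient_id"])]
    panel = build_panel(train_records, config.simulation.start_year, config.simulation.end_year)
    models = fit_exposure_models(panel)
    weights = compute_iptw(panel, models)
    weights.to_csv(outdir / "weights.csv", index=False)
    w_tr = (
        weights.set_index("patient_id")["weight"].reindex(train["patient_id"]).to_numpy(float)
    )
    X_tr, encoding = encode_features(train[FEATURE_COLUMNS])
    msm = fit_msm(X_tr, y_tr, w_tr)
    rank_msm = rank_msm_features(msm)
    rank_msm.to_csv(outdir / "msm_feature_ranking.csv", index=False)
    coef = pd.DataFrame({"term": msm.params.index, "coefficient": msm.params.to_numpy(),
                         "std_err": msm.bse.to_numpy(), "p_value": msm.pvalues.to_numpy()})
    coef.to_csv(outdir / "msm_fit.csv", index=False)
    (outdir / "encoding.json").write_text(json.dumps(encoding, indent=1, sort_keys=True))
    manifest["stages"]["weights"]["mean_weight"] = weights.attrs["mean_weight"]
    manifest["stages"]["weights"]["n_clipped"] = weights.attrs["n_clipped"]
    _done("weights", t0, len(weights))

    # --- MLP + ensemble ---
    _, t0 = _stage("fit")
    ipm = fit_ipm(
        train, y_tr, w_tr,
        mlp_hyperparams=config.mlp,
        gbc_hyperparams=config.gbc,
        threshold=config.threshold,
    )
    rank_mlp = rank_mlp_features(ipm.mlp_model)
    rank_mlp.to_csv(outdir / "mlp_feature_ranking.csv", index=False)
    _done("fit", t0, len(train))

    # --- evaluation on the held-out 20% ---
    eval_seed, t0 = _stage("evaluate")
    X_te_enc, _ = encode_features(test[FEATURE_COLUMNS])
    p_msm = predict_msm(ipm.msm_fit, X_te_enc)
    p_mlp = predict_mlp(ipm.mlp_model, test[FEATURE_COLUMNS])
    p_ipm, c_ipm = predict_ipm(ipm, test)
    reports = {}
    for name, proba in (("MSM", p_msm), ("MLP", p_mlp), ("IPM", p_ipm)):
        pred = (proba >= config.threshold).astype(int)
        rep = confusion_and_metrics(y_te, pred)
        auc_rep = auc_with_ci(y_te, proba, seed=eval_seed, n_boot=config.n_bootstrap)
        rep.auc, rep.auc_ci, rep.roc_points = auc_rep.auc, auc_rep.auc_ci, auc_rep.roc_points
        reports[name] = rep
        rep.roc_points.to_csv(outdir / f"roc_{name.lower()}.csv", index=False)
    comparison = compare_models(reports)
    comparison.to_csv(outdir / "model_comparison.csv", index=False)
    eval_json = {
        name: _round_report(rep.as_dict(), config.report_decimals)
        for name, rep in reports.items()
    }
    (outdir / "evaluation.json").write_text(json.dumps(eval_json, indent=1, sort_keys=True))
    if make_plots:
        _plot_roc(reports, outdir / "roc_curves.png")
    _done("evaluate", t0, len(test))

    # --- sensitivity protocol ---
    if config.run_sensitivity:
        sens_seed, t0 = _stage("sensitivity")
        imp = config.imputation
        imp_cfg = type(imp)(m=imp.m, burn_in=imp.burn_in, seed=sens_seed, pooling=imp.pooling)
        sens = run_sensitivity(
            cohort,
            weights_by_patient=weights.set_index("patient_id")["weight"],
            split_seed=split_seed,
            rate=config.sensitivity_rate,
            imputation=imp_cfg,
            mlp_hyperparams=config.mlp,
            gbc_hyperparams=config.gbc,
            mask_seed=config.stage_seed("mask"),
            n_boot=config.n_bootstrap,
            threshold=config.threshold,
        )
        sens_json = {
            "mode": sens.mode,
            "pooling": sens.pooling,
            "ipm": _round_report(sens.ipm, config.report_decimals),
            "mlp_only": _round_report(sens.mlp_only, config.report_decimals),
        }
        (outdir / "sensitivity.json").write_text(json.dumps(sens_json, indent=1, sort_keys=True))
        _done("sensitivity", t0, len(cohort))

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["artifacts"][path.name] = _file_hash(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _plot_roc(reports: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        ax.plot(rep.roc_points["fpr"], rep.roc_points["tpr"], label=f"{name} (AUC {rep.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
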