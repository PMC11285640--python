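"""Robustness protocol: distort 40% of predictor cells, multiply impute, re-evaluate.

Missing cells are filled by a data-augmentation Gibbs sampler under a
joint multivariate-normal model: each sweep draws (mean, covariance)
from their posterior given the current completed data (Jeffreys prior →
normal–inverse-Wishart updates), then redraws the missing cells from
their conditional normal given the observed cells of the row.
Categorical predictors are coded to level indices before imputation and
decoded by nearest-level rounding afterwards — a known mismatch of the
normal model, accepted as the faithful compromise.  Chains are seeded
and independent across the m imputations.

The comparison refits the full ensemble (with the marginal-structural
pMSM feature) and an MLP-only model on each completed table with
identical splits and seeds, then pools metrics across imputations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_builder import CATEGORICAL_LEVELS, FEATURE_COLUMNS, NUMERIC_FEATURES
from .ensemble_ipm import GbcHyperparams, fit_ipm, predict_ipm
from .evaluation import auc_with_ci, confusion_and_metrics
from .neural_model import MlpHyperparams, predict_mlp
from .synthetic_claims import inject_missingness

__all__ = ["ImputationConfig", "impute", "run_sensitivity", "SensitivityResult"]


@dataclass
class ImputationConfig:
    """Multiple-imputation settings."""

    m: int = 5
    burn_in: int = 50
    seed: int = 0
    pooling: str = "per-dataset-mean"  # or "single-dataset"

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("number of imputations m must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.pooling not in ("per-dataset-mean", "single-dataset"):
            raise ValueError("pooling must be 'per-dataset-mean' or 'single-dataset'")


def _code_table(df: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, dict]:
    """Numeric coding: categoricals → level index, numerics unchanged."""
    coded = np.empty((len(df), len(columns)))
    meta = {}
    for j, col in enumerate(columns):
        if col in CATEGORICAL_LEVELS:
            levels = list(CATEGORICAL_LEVELS[col])
            mapping = {lv: i for i, lv in enumerate(levels)}
            coded[:, j] = [mapping.get(v, np.nan) if pd.notna(v) else np.nan for v in df[col]]
            meta[col] = levels
        else:
            coded[:, j] = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
            meta[col] = None
    return coded, meta


def _decode_table(coded: np.ndarray, columns: list[str], meta: dict, index) -> pd.DataFrame:
    out = {}
    for j, col in enumerate(columns):
        levels = meta[col]
        if levels is not None:
            idx = np.clip(np.rint(coded[:, j]), 0, len(levels) - 1).astype(int)
            out[col] = [levels[i] for i in idx]
        else:
            vals = coded[:, j]
            out[col] = np.maximum(np.rint(vals), 0).astype(int) if col in NUMERIC_FEATURES else vals
    return pd.DataFrame(out, index=index)


def _gibbs_chain(
    data: np.ndarray, miss: np.ndarray, burn_in: int, rng: np.random.Generator
) -> np.ndarray:
    """One data-augmentation chain; returns a completed matrix.

    Each sweep draws (mu, Sigma) from their posterior given the current
    completed matrix (Jeffreys prior), then redraws the missing cells
    column by column from the univariate conditional normal of that
    column given all others — a systematic-scan Gibbs update of the same
    joint MVN model, vectorized over rows.
    """
    n, p = data.shape
    X = data.copy()
    col_means = np.nanmean(data, axis=0)
    for j in range(p):
        X[miss[:, j], j] = col_means[j]

    ridge = 1e-6
    others = [np.delete(np.arange(p), j) for j in range(p)]
    for _ in range(burn_in + 1):
        xbar = X.mean(axis=0)
        S = np.cov(X, rowvar=False, ddof=1) * (n - 1)
        S = S + ridge * np.eye(p)
        # Jeffreys prior: Sigma | X ~ InvWishart(n-1, S); mu | Sigma ~ N(xbar, Sigma/n)
        sigma = sps.invwishart.rvs(df=max(n - 1, p + 2), scale=S, random_state=rng)
        sigma = np.atleast_2d(sigma) + ridge * np.eye(p)
        mu = rng.multivariate_normal(xbar, sigma / n, method="cholesky")

        for j in range(p):
            rows = np.flatnonzero(miss[:, j])
            if rows.size == 0:
                continue
            o = others[j]
            beta = np.linalg.solve(sigma[np.ix_(o, o)], sigma[o, j])
            var = float(sigma[j, j] - sigma[j, o] @ beta)
            var = max(var, ridge)
            cond_mu = mu[j] + (X[np.ix_(rows, o)] - mu[o]) @ beta
            X[rows, j] = cond_mu + np.sqrt(var) * rng.standard_normal(rows.size)
    return X


def impute(
    table: pd.DataFrame,
    config: ImputationConfig,
    predictor_columns: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Draw ``m`` completed tables from the MVN data-augmentation sampler.

    Missingness must be confined to predictor columns; observed cells
    are returned unchanged.  A column with every cell missing cannot be
    imputed and raises.  With no missing cells the input is returned as
    ``m`` identical copies.
    """
    cols = predictor_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    coded, meta = _code_table(table, cols)
    miss = np.isnan(coded)
    all_missing = [cols[j] for j in range(len(cols)) if miss[:, j].all()]
    if all_missing:
        raise ValueError(f"column(s) with all cells missing cannot be imputed: {all_missing}")
    if not miss.any():
        return [table.copy() for _ in range(config.m)]

    completed: list[pd.DataFrame] = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    for k in range(config.m):
        rng = np.random.default_rng(seeds[k])
        filled = _gibbs_chain(coded, miss, config.burn_in, rng)
        filled[~miss] = coded[~miss]  # observed cells are sacrosanct
        out = table.copy()
        decoded = _decode_table(filled, cols, meta, table.index)
        for col in cols:
            out[col] = decoded[col]
        # restore observed categorical cells exactly (rounding never applies)
        for j, col in enumerate(cols):
            obs = ~miss[:, j]
            out.loc[out.index[obs], col] = table.loc[table.index[obs], col].to_numpy()
        completed.append(out)
    return completed


@dataclass
class SensitivityResult:
    """Paired pooled reports of the full ensemble vs the MLP-only model."""

    ipm: dict
    mlp_only: dict
    mode: str
    pooling: str
    per_imputation: list = field(default_factory=list)


def _pool(reports: list[dict]) -> dict:
    keys = ["accuracy", "precision", "recall", "specificity", "f1", "auc"]
    pooled = {}
    for k in keys:
        vals = [r[k] for r in reports if r.get(k) is not None]
        pooled[k] = float(np.mean(vals)) if vals else None
    ci_lo = [r["auc_ci"][0] for r in reports if r.get("auc_ci")]
    ci_hi = [r["auc_ci"][1] for r in reports if r.get("auc_ci")]
    pooled["auc_ci"] = [float(np.mean(ci_lo)), float(np.mean(ci_hi))] if ci_lo else None
    pooled["m"] = len(reports)
    return pooled


def _evaluate(y_true, proba, pred, *, with_ci: bool, seed: int, n_boot: int) -> dict:
    rep = confusion_and_metrics(y_true, pred).as_dict()
    if with_ci:
        auc_rep = auc_with_ci(y_true, proba, seed=seed, n_boot=n_boot)
        rep["auc"] = auc_rep.auc
        rep["auc_ci"] = list(auc_rep.auc_ci)
    else:
        from sklearn.metrics import roc_auc_score

        rep["auc"] = float(roc_auc_score(y_true, proba))
        rep["auc_ci"] = None
    return rep


def run_sensitivity(
    cohort: pd.DataFrame,
    weights_by_patient: pd.Series,
    split_seed: int,
    rate: float = 0.4,
    imputation: ImputationConfig | None = None,
    mlp_hyperparams: MlpHyperparams | None = None,
    gbc_hyperparams: GbcHyperparams | None = None,
    mask_seed: int | None = None,
    refit: bool = True,
    primary_ipm=None,
    with_ci: bool = True,
    n_boot: int = 2000,
    threshold: float = 0.5,
) -> SensitivityResult:
    """Distort → impute → re-evaluate the ensemble with and without the MSM arm.

    The predictor cells of the analysis table are masked at ``rate``
    (MCAR), multiply imputed, and both the full ensemble (IPM, including
    the IPTW-weighted marginal-structural probability feature) and an
    MLP-only model are refitted and evaluated on each completed table
    with the identical train/test split.  ``refit=False`` instead
    re-scores the already-fitted primary models (``primary_ipm``
    required) on the imputed test rows.  Metrics are pooled per the
    imputation config.  With ``rate=0`` the protocol reduces exactly to
    the primary analysis.
    """
    from .ensemble_ipm import split_cohort

    imp = imputation or ImputationConfig()
    if mask_seed is None:
        mask_seed = imp.seed + 1
    if not refit and primary_ipm is None:
        raise ValueError("re-score mode needs the fitted primary ensemble (primary_ipm)")

    masked = inject_missingness(cohort, rate, seed=mask_seed)
    completed = impute(masked, imp)
    if imp.pooling == "single-dataset":
        completed = completed[:1]

    ipm_reports: list[dict] = []
    mlp_reports: list[dict] = []
    per_imp = []
    for k, table in enumerate(completed):
        train, test = split_cohort(table, seed=split_seed)
        y_tr = train["outcome"].to_numpy(int)
        y_te = test["outcome"].to_numpy(int)
        w_tr = weights_by_patient.reindex(train["patient_id"]).to_numpy(float)
        if refit:
            ipm = fit_ipm(
                train, y_tr, w_tr,
                mlp_hyperparams=mlp_hyperparams,
                gbc_hyperparams=gbc_hyperparams,
                threshold=threshold,
            )
            mlp = ipm.mlp_model
        else:
            ipm = primary_ipm
            mlp = primary_ipm.mlp_model
        p_ipm, c_ipm = predict_ipm(ipm, test)
        p_mlp = predict_mlp(mlp, test[ipm.feature_columns])
        c_mlp = (p_mlp >= threshold).astype(int)
        rep_ipm = _evaluate(y_te, p_ipm, c_ipm, with_ci=with_ci, seed=imp.seed + 100 + k, n_boot=n_boot)
        rep_mlp = _evaluate(y_te, p_mlp, c_mlp, with_ci=with_ci, seed=imp.seed + 200 + k, n_boot=n_boot)
        ipm_reports.append(rep_ipm)
        mlp_reports.append(rep_mlp)
        per_imp.append({"imputation": k, "ipm": rep_ipm, "mlp_only": rep_mlp})

    return SensitivityResult(
        ipm=_pool(ipm_reports),
        mlp_only=_pool(mlp_reports),
        mode="refit" if refit else "re-score",
        pooling=imp.pooling,
        per_imputation=per_imp,
    )
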