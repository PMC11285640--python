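"""Stabilized inverse-probability-of-treatment weights and the marginal structural model.

The stabilized weight for a patient with exposure history E_0..E_T and
covariates X is

    sw = prod_{t=0}^{T}  P(E_t | E_{t-1}, X_0) / P(E_t | E_{t-1}, X_0, X_{t-1})

with the probability of the *realized* exposure level (p if E_t = 1,
1 - p otherwise) in both numerator and denominator and the lagged terms
omitted at t = 0.  The numerator conditions on baseline covariates X_0 as
well as past exposure; ``numerator_mode="marginal"`` switches to the
conventional covariate-free stabilized numerator.

Numerator and denominator probabilities come from pooled-over-time
logistic regressions with year fixed effects (per-year fits available via
``per_year=True``).  Lags where the exposure is degenerate (no variation)
contribute a factor of exactly 1 to both products.  The outcome model is
a linear probability model fitted by weighted least squares with the
stabilized weights and heteroskedasticity-robust standard errors;
predictions are the linear predictor clipped to [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_builder import encode_features
from .synthetic_claims import PatientRecord
from . import cohort_builder

logger = logging.getLogger(__name__)

__all__ = [
    "build_panel",
    "fit_exposure_models",
    "compute_iptw",
    "fit_msm",
    "predict_msm",
    "rank_msm_features",
    "ExposureModels",
    "MsmFit",
    "BASELINE_PREFIX",
    "TV_COLUMNS",
]

BASELINE_PREFIX = "x0_"
TV_COLUMNS = ("tv_comorbid", "tv_util", "tv_cum_mdd")

_DEMO_COLS = ("age_group", "gender", "race", "rural_urban", "hpsa")


def build_panel(
    records: list[PatientRecord],
    start_year: int,
    end_year: int,
    registry=None,
) -> pd.DataFrame:
    """Expand claim records into a rectangular patient × year exposure panel.

    One row per patient per year index t = 0..T (t = 0 is the first window
    year).  ``E`` is 1 iff the patient has an MDD-classified claim in that
    year.  Time-varying covariates use claims from years <= t only:
    ``tv_comorbid`` (any non-MDD/non-AD claim that year), ``tv_util``
    (utilization days that year), ``tv_cum_mdd`` (cumulative MDD claim
    count through t).  Baseline demographics are one-hot encoded with the
    ``x0_`` prefix.
    """
    if registry is None:
        registry = cohort_builder.DEFAULT_REGISTRY
    if end_year < start_year:
        raise ValueError("empty year window")
    years = np.arange(start_year, end_year + 1)
    T = len(years)

    claim_rows = []
    for rec in records:
        for c in rec.claims:
            if start_year <= c.year <= end_year:
                cls = cohort_builder.classify_code(c.code_system, c.code, registry)
                claim_rows.append((rec.patient_id, c.year, cls, c.utilization_days))
    claims = pd.DataFrame(
        claim_rows, columns=["patient_id", "year", "class", "utilization_days"]
    )

    ids = [rec.patient_id for rec in records]
    base = pd.DataFrame(
        {
            "patient_id": np.repeat(ids, T),
            "t": np.tile(np.arange(T), len(ids)),
            "year": np.tile(years, len(ids)),
        }
    )

    if len(claims):
        mdd = (
            claims[claims["class"] == "MDD"]
            .groupby(["patient_id", "year"])
            .size()
            .rename("n_mdd")
        )
        oth = (
            claims[claims["class"] == "OTHER"]
            .groupby(["patient_id", "year"])
            .size()
            .rename("n_other")
        )
        util = (
            claims.groupby(["patient_id", "year"])["utilization_days"]
            .sum()
            .rename("tv_util")
        )
        base = (
            base.merge(mdd, left_on=["patient_id", "year"], right_index=True, how="left")
            .merge(oth, left_on=["patient_id", "year"], right_index=True, how="left")
            .merge(util, left_on=["patient_id", "year"], right_index=True, how="left")
        )
    else:
        base["n_mdd"] = 0.0
        base["n_other"] = 0.0
        base["tv_util"] = 0.0
    base[["n_mdd", "n_other", "tv_util"]] = base[["n_mdd", "n_other", "tv_util"]].fillna(0.0)
    base["E"] = (base["n_mdd"] > 0).astype(int)
    base["tv_comorbid"] = (base["n_other"] > 0).astype(int)
    base["tv_cum_mdd"] = base.groupby("patient_id", sort=False)["n_mdd"].cumsum()
    base = base.drop(columns=["n_mdd", "n_other"])

    demo = pd.DataFrame(
        {col: [getattr(rec, col) for rec in records] for col in _DEMO_COLS},
        index=ids,
    )
    enc, _ = encode_features(demo, feature_columns=list(_DEMO_COLS))
    enc.columns = [BASELINE_PREFIX + c for c in enc.columns]
    panel = base.merge(enc, left_on="patient_id", right_index=True, how="left")
    return panel.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)


class _LogitModel:
    """Logistic fit with a penalized fallback under separation/singularity."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        self.params: np.ndarray | None = None
        self.fallback = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_LogitModel":
        Xc = sm.add_constant(X, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e3:
                raise ValueError("diverging coefficients (separation)")
            self.params = np.asarray(res.params)
        except Exception:  # separation, singular Hessian, non-convergence
            logger.warning(
                "exposure logit failed (likely perfect separation); "
                "falling back to an L2-penalized fit"
            )
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0, max_iter=2000)
            lr.fit(X, y)
            self.params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
            self.fallback = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = sm.add_constant(X, has_constant="add")
        eta = Xc @ self.params
        return 1.0 / (1.0 + np.exp(-eta))


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


@dataclass
class ExposureModels:
    """Fitted numerator/denominator exposure-probability models."""

    numerator_mode: str
    per_year: bool
    num_columns: list[str] = field(default_factory=list)
    den_columns: list[str] = field(default_factory=list)
    # pooled fits (per_year=False) or {t: fit} maps (per_year=True)
    num_fit: object = None
    den_fit: object = None
    degenerate_ts: list[int] = field(default_factory=list)
    baseline_cols: list[str] = field(default_factory=list)
    t0: dict = field(default_factory=dict)


def _with_lags(panel: pd.DataFrame) -> pd.DataFrame:
    df = panel.sort_values(["patient_id", "t"], kind="mergesort").copy()
    g = df.groupby("patient_id", sort=False)
    df["E_prev"] = g["E"].shift(1)
    for col in TV_COLUMNS:
        df[col + "_prev"] = g[col].shift(1)
    return df


def fit_exposure_models(
    panel: pd.DataFrame,
    numerator_mode: str = "covariate",
    per_year: bool = False,
) -> ExposureModels:
    """Fit the numerator and denominator exposure models.

    Numerator: E_t on (E_{t-1}, X_0); denominator: E_t on
    (E_{t-1}, X_0, X_{t-1}), pooled over t >= 1 with year fixed effects
    (or one fit per year with ``per_year=True``).  Year indices where the
    exposure is degenerate are recorded and contribute probability 1 to
    both weight products.  With ``numerator_mode="marginal"`` the
    numerator drops the baseline covariates (conventional stabilized
    weights), which makes the t = 0 factor informative; under the default
    covariate numerator, numerator and denominator coincide at t = 0 and
    the factor cancels to 1 exactly.
    """
    if numerator_mode not in ("covariate", "marginal"):
        raise ValueError("numerator_mode must be 'covariate' or 'marginal'")
    df = _with_lags(panel)
    baseline_cols = [c for c in panel.columns if c.startswith(BASELINE_PREFIX)]
    tv_prev = [c + "_prev" for c in TV_COLUMNS]

    degenerate = [
        int(t) for t, grp in df.groupby("t") if grp["E"].nunique() < 2
    ]
    models = ExposureModels(
        numerator_mode=numerator_mode,
        per_year=per_year,
        degenerate_ts=degenerate,
        baseline_cols=baseline_cols,
    )

    fit_rows = df[(df["t"] >= 1) & (~df["t"].isin(degenerate))]
    if len(fit_rows):
        year_d = pd.get_dummies(fit_rows["t"], prefix="t", drop_first=True, dtype=float)
        num_base = ["E_prev"] + ([] if numerator_mode == "marginal" else baseline_cols)
        num_X = _drop_constant(pd.concat([fit_rows[num_base], year_d], axis=1))
        den_X = _drop_constant(
            pd.concat(
                [fit_rows[["E_prev"] + baseline_cols + list(tv_prev)], year_d], axis=1
            )
        )
        y = fit_rows["E"].to_numpy(float)
        if per_year:
            models.num_fit, models.den_fit = {}, {}
            for t, grp in fit_rows.groupby("t"):
                nX = _drop_constant(grp[[c for c in num_X.columns if not c.startswith("t_")]])
                dX = _drop_constant(grp[[c for c in den_X.columns if not c.startswith("t_")]])
                models.num_fit[int(t)] = _LogitModel(list(nX.columns)).fit(
                    nX.to_numpy(float), grp["E"].to_numpy(float)
                )
                models.den_fit[int(t)] = _LogitModel(list(dX.columns)).fit(
                    dX.to_numpy(float), grp["E"].to_numpy(float)
                )
            models.num_columns = [c for c in num_X.columns if not c.startswith("t_")]
            models.den_columns = [c for c in den_X.columns if not c.startswith("t_")]
        else:
            models.num_columns = list(num_X.columns)
            models.den_columns = list(den_X.columns)
            models.num_fit = _LogitModel(models.num_columns).fit(num_X.to_numpy(float), y)
            models.den_fit = _LogitModel(models.den_columns).fit(den_X.to_numpy(float), y)

    # t = 0: no lagged terms exist, so numerator and denominator both
    # condition on X_0 at most.  Under the covariate numerator they are
    # identical and cancel; under the marginal numerator fit both.
    t0_rows = df[df["t"] == 0]
    if numerator_mode == "marginal" and 0 not in degenerate and len(t0_rows):
        nX = pd.DataFrame(index=t0_rows.index)  # intercept-only
        dX = _drop_constant(t0_rows[baseline_cols])
        y0 = t0_rows["E"].to_numpy(float)
        models.t0 = {
            "num": _LogitModel([]).fit(np.empty((len(t0_rows), 0)), y0),
            "den": _LogitModel(list(dX.columns)).fit(dX.to_numpy(float), y0),
            "den_columns": list(dX.columns),
        }
    return models


def _realized(p: np.ndarray, e: np.ndarray) -> np.ndarray:
    return np.where(e == 1, p, 1.0 - p)


def _predict_lagged(models: ExposureModels, df: pd.DataFrame, which: str) -> np.ndarray:
    """Probability of E_t = 1 for rows with t >= 1 (degenerate ts excluded)."""
    fit = models.num_fit if which == "num" else models.den_fit
    cols = models.num_columns if which == "num" else models.den_columns
    if models.per_year:
        p = np.empty(len(df))
        for t, grp in df.groupby("t"):
            sub_fit = fit[int(t)]
            X = grp.reindex(columns=sub_fit.columns, fill_value=0.0).to_numpy(float)
            p[df["t"].to_numpy() == t] = sub_fit.predict(X)
        return p
    year_d = pd.get_dummies(df["t"], prefix="t", dtype=float)
    X = pd.concat([df, year_d], axis=1).reindex(columns=cols, fill_value=0.0)
    return fit.predict(X.to_numpy(float))


def compute_iptw(
    panel: pd.DataFrame,
    models: ExposureModels,
    floor: float = 1e-6,
) -> pd.DataFrame:
    """Per-patient stabilized weights from fitted exposure models.

    Returns one row per patient with the weight, numerator and
    denominator log-probabilities (diagnostics), and reports the number
    of denominator probabilities clipped at the floor via the frame's
    ``attrs`` (keys ``n_clipped``, ``mean_weight``,
    ``extreme_weight_fraction``).
    """
    df = _with_lags(panel)
    e = df["E"].to_numpy(float)
    num_p = np.ones(len(df))
    den_p = np.ones(len(df))

    lag_mask = (df["t"] >= 1) & (~df["t"].isin(models.degenerate_ts))
    if lag_mask.any() and models.num_fit is not None:
        sub = df[lag_mask]
        num_p[lag_mask.to_numpy()] = _realized(
            _predict_lagged(models, sub, "num"), e[lag_mask.to_numpy()]
        )
        den_p[lag_mask.to_numpy()] = _realized(
            _predict_lagged(models, sub, "den"), e[lag_mask.to_numpy()]
        )

    t0_mask = (df["t"] == 0).to_numpy()
    if models.t0:
        sub = df[t0_mask]
        p_num = models.t0["num"].predict(np.empty((len(sub), 0)))
        dX = sub.reindex(columns=models.t0["den_columns"], fill_value=0.0).to_numpy(float)
        p_den = models.t0["den"].predict(dX)
        num_p[t0_mask] = _realized(p_num, e[t0_mask])
        den_p[t0_mask] = _realized(p_den, e[t0_mask])

    n_clipped = int((den_p < floor).sum())
    if n_clipped:
        logger.warning("clipped %d denominator probabilities at %g", n_clipped, floor)
    den_p = np.clip(den_p, floor, None)
    num_p = np.clip(num_p, floor, None)

    df = df.assign(_lognum=np.log(num_p), _logden=np.log(den_p))
    agg = df.groupby("patient_id", sort=False)[["_lognum", "_logden"]].sum()
    weights = pd.DataFrame(
        {
            "patient_id": agg.index,
            "weight": np.exp(agg["_lognum"] - agg["_logden"]).to_numpy(),
            "numerator_logprob": agg["_lognum"].to_numpy(),
            "denominator_logprob": agg["_logden"].to_numpy(),
        }
    ).reset_index(drop=True)
    if not np.all(np.isfinite(weights["weight"])) or np.any(weights["weight"] <= 0):
        raise RuntimeError("non-finite or non-positive stabilized weight produced")
    weights.attrs["n_clipped"] = n_clipped
    weights.attrs["mean_weight"] = float(weights["weight"].mean())
    weights.attrs["extreme_weight_fraction"] = float(
        ((weights["weight"] > 10) | (weights["weight"] < 0.1)).mean()
    )
    return weights


@dataclass
class MsmFit:
    """Weighted least-squares marginal structural model fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    columns: list[str]
    dropped: list[str]
    weight_summary: dict


def fit_msm(X: pd.DataFrame, y: np.ndarray, weights: np.ndarray) -> MsmFit:
    """Linear probability model of the outcome, weighted by the IPTW.

    Aliased (rank-deficient) design columns are dropped with a warning;
    standard errors are heteroskedasticity-robust (HC1).
    """
    w = np.asarray(weights, float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    Xd = X.astype(float).copy()

    dropped: list[str] = []
    arr = Xd.to_numpy()
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    _, R, piv = _qr_pivot(np.column_stack([np.ones(len(Xd)), arr / scale]))
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps * 100
    rank = int((diag > tol).sum())
    if rank < len(piv):
        alias_idx = sorted(piv[rank:])
        for j in alias_idx:
            if j == 0:
                continue
            dropped.append(Xd.columns[j - 1])
        if dropped:
            warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=2)
            Xd = Xd.drop(columns=dropped)

    design = sm.add_constant(Xd, has_constant="add")
    res = sm.WLS(np.asarray(y, float), design, weights=w).fit(cov_type="HC1")
    return MsmFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        columns=list(Xd.columns),
        dropped=dropped,
        weight_summary={
            "mean": float(np.mean(w)),
            "sd": float(np.std(w)),
            "min": float(np.min(w)),
            "max": float(np.max(w)),
        },
    )


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


def predict_msm(fit: MsmFit, X: pd.DataFrame) -> np.ndarray:
    """Linear predictor clipped to [0, 1] (pMSM probabilities)."""
    missing = [c for c in fit.columns if c not in X.columns]
    if missing:
        raise ValueError(f"prediction frame is missing design columns: {missing}")
    design = sm.add_constant(X[fit.columns].astype(float), has_constant="add")
    eta = design.to_numpy() @ fit.params.reindex(design.columns).to_numpy()
    return np.clip(eta, 0.0, 1.0)


def rank_msm_features(fit: MsmFit, alpha: float = 0.05, aggregate: bool = False) -> pd.DataFrame:
    """Features sorted by WLS coefficient, descending; p < alpha starred.

    ``aggregate=True`` collapses one-hot indicator columns of one
    categorical variable to a single row using the largest-|coefficient|
    indicator (a compact per-variable view of the ranking).
    """
    rows = pd.DataFrame(
        {
            "feature": fit.columns,
            "coefficient": [fit.params[c] for c in fit.columns],
            "std_err": [fit.bse[c] for c in fit.columns],
            "p_value": [fit.pvalues[c] for c in fit.columns],
        }
    )
    if aggregate:
        rows["variable"] = rows["feature"].str.split("=").str[0]
        idx = rows.groupby("variable")["coefficient"].apply(lambda s: s.abs().idxmax())
        rows = rows.loc[idx.to_numpy()].copy()
        rows["feature"] = rows.pop("variable")
    rows["significant"] = rows["p_value"] < alpha
    rows = rows.sort_values("coefficient", ascending=False, kind="mergesort")
    rows["rank"] = np.arange(1, len(rows) + 1)
    return rows.reset_index(drop=True)
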