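"""The integrated predictive model: stacking pANN and pMSM into gradient-boosted trees.

The meta-learner receives exactly two features per observation — the
perceptron's predicted probability (pANN) and the marginal structural
model's predicted probability (pMSM) — and combines them with a
gradient-boosted classifier (100 trees of depth 3, learning rate 0.01,
60% subsampling without replacement).  Base-model training predictions
are in-sample by default; a cross-fitted variant (out-of-fold stack
features, a leakage control) is available behind ``cross_fit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .causal_weights import MsmFit, fit_msm, predict_msm
from .cohort_builder import FEATURE_COLUMNS, encode_features
from .neural_model import MlpHyperparams, MlpModel, fit_mlp, predict_mlp

__all__ = ["GbcHyperparams", "IpmModel", "split_cohort", "fit_ipm", "predict_ipm"]


@dataclass
class GbcHyperparams:
    """Meta-learner (gradient boosting) hyperparameters."""

    random_state: int = 28
    n_estimators: int = 100
    learning_rate: float = 0.01
    max_depth: int = 3
    subsample: float = 0.6


def split_cohort(
    cohort: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    outcome_col: str = "outcome",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome-stratified train/test split (per-group 80/20 by default).

    Within each outcome group, ``round(train_fraction * n_group)``
    patients go to training; the partition is disjoint, exhaustive and
    seeded.  A 282 + 282 cohort yields 226 training and 56 test patients
    per group.
    """
    groups = cohort[outcome_col].unique()
    if len(groups) < 2:
        raise ValueError("both outcome groups must be present to split")
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for g in sorted(groups):
        idx = cohort.index[cohort[outcome_col] == g].to_numpy()
        n_train = int(round(train_fraction * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(
                f"outcome group {g} (n={len(idx)}) is too small for a "
                f"{train_fraction:.0%} split"
            )
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return cohort.loc[sorted(train_idx)], cohort.loc[sorted(test_idx)]


@dataclass
class IpmModel:
    """Fitted ensemble triple: MSM fit + perceptron + gradient booster."""

    msm_fit: MsmFit
    mlp_model: MlpModel
    booster: GradientBoostingClassifier
    gbc_hyperparams: GbcHyperparams
    threshold: float = 0.5
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    def stack_features(self, features: pd.DataFrame) -> pd.DataFrame:
        """The [pANN, pMSM] probability pair per observation."""
        X_enc, _ = encode_features(features[self.feature_columns])
        p_ann = predict_mlp(self.mlp_model, features[self.feature_columns])
        p_msm = predict_msm(self.msm_fit, X_enc)
        return pd.DataFrame({"pANN": p_ann, "pMSM": p_msm}, index=features.index)


def fit_ipm(
    train: pd.DataFrame,
    y_train: np.ndarray,
    weights: np.ndarray,
    mlp_hyperparams: MlpHyperparams | None = None,
    gbc_hyperparams: GbcHyperparams | None = None,
    threshold: float = 0.5,
    cross_fit: bool = True,
    n_folds: int = 5,
) -> IpmModel:
    """Fit the full ensemble on the training partition only.

    Both base models are fitted on exactly the supplied training rows
    (the marginal structural model takes the per-patient stabilized
    weights).  The meta-learner's stack features are out-of-fold base
    predictions from ``n_folds``-fold refits of the same training data
    (cross-fitting): in-sample base probabilities overstate the more
    flexible base model and demonstrably drag the ensemble below its
    best base, so the leakage-free stack is the default.
    ``cross_fit=False`` gives the naive in-sample variant.
    """
    gbc = gbc_hyperparams or GbcHyperparams()
    y = np.asarray(y_train, int)
    w = np.asarray(weights, float)
    if len(train) != len(y) or len(train) != len(w):
        raise ValueError("train, y_train and weights must align row-wise")

    feats = train[FEATURE_COLUMNS]
    X_enc, _ = encode_features(feats)
    msm = fit_msm(X_enc, y, w)
    mlp = fit_mlp(feats, y, mlp_hyperparams)

    if cross_fit:
        from sklearn.model_selection import StratifiedKFold

        p_ann = np.empty(len(y))
        p_msm = np.empty(len(y))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=gbc.random_state)
        for tr, te in skf.split(np.zeros(len(y)), y):
            X_tr, _ = encode_features(feats.iloc[tr])
            X_te, _ = encode_features(feats.iloc[te])
            fold_msm = fit_msm(X_tr, y[tr], w[tr])
            fold_mlp = fit_mlp(feats.iloc[tr], y[tr], mlp_hyperparams)
            p_msm[te] = predict_msm(fold_msm, X_te)
            p_ann[te] = predict_mlp(fold_mlp, feats.iloc[te])
    else:
        p_ann = predict_mlp(mlp, feats)
        p_msm = predict_msm(msm, X_enc)
    if not (np.all(np.isfinite(p_ann)) and np.all(np.isfinite(p_msm))):
        raise ValueError("base-model probability missing or non-finite for some row")

    stack = np.column_stack([p_ann, p_msm])
    booster = GradientBoostingClassifier(
        random_state=gbc.random_state,
        n_estimators=gbc.n_estimators,
        learning_rate=gbc.learning_rate,
        max_depth=gbc.max_depth,
        subsample=gbc.subsample,
    )
    booster.fit(stack, y)
    return IpmModel(
        msm_fit=msm,
        mlp_model=mlp,
        booster=booster,
        gbc_hyperparams=gbc,
        threshold=threshold,
    )


def predict_ipm(model: IpmModel, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """End-to-end prediction on raw feature rows.

    The base models are applied internally (the caller never supplies
    stack features); returns (probability, class) with the model's
    threshold (0.5 by default).  Test-time prediction needs no weights:
    the stabilized weights act only at fitting time.
    """
    missing = [c for c in model.feature_columns if c not in features.columns]
    if missing:
        raise ValueError(f"prediction table is missing feature columns: {missing}")
    stack = model.stack_features(features)
    proba = model.booster.predict_proba(stack.to_numpy())
    pos_idx = int(np.where(model.booster.classes_ == 1)[0][0])
    p = proba[:, pos_idx]
    return p, (p >= model.threshold).astype(int)
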