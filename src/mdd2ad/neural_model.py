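"""Multilayer-perceptron base learner and first-layer-weight feature importance.

One hidden layer of 6 ReLU units trained with L-BFGS — a configuration
suited to small tabular cohorts — producing the pANN probability of
progression.  Feature importance is the sum of absolute first-layer
weights per input, with a one-sample t-test of the signed weights
against mean zero for a (low-powered, by construction) significance
screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .cohort_builder import NUMERIC_FEATURES, encode_features

__all__ = ["MlpHyperparams", "MlpModel", "fit_mlp", "predict_mlp", "rank_mlp_features"]


@dataclass
class MlpHyperparams:
    """Hyperparameters of the perceptron base learner."""

    activation: str = "relu"
    solver: str = "lbfgs"
    alpha: float = 1e-8
    tol: float = 1e-3
    learning_rate_init: float = 0.1
    hidden_layer_spec: tuple[int, ...] = (6,)
    max_iter: int = 1200
    random_state: int = 4

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden_layer_spec):
            raise ValueError("hidden layer sizes must be positive")


@dataclass
class MlpModel:
    """Fitted perceptron with its leakage-safe preprocessing state."""

    clf: MLPClassifier
    scaler: StandardScaler | None
    feature_columns: list[str]
    numeric_columns: list[str]
    encoding: dict = field(default_factory=dict)
    converged: bool = True

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        if features.select_dtypes(include=["object", "category"]).shape[1]:
            X, _ = encode_features(features)
        else:
            X = features
        missing = [c for c in self.feature_columns if c not in X.columns]
        if missing:
            raise ValueError(f"feature matrix is missing columns: {missing}")
        X = X[self.feature_columns].astype(float)
        if not np.all(np.isfinite(X.to_numpy())):
            raise ValueError("non-finite values in feature matrix")
        arr = X.to_numpy()
        if self.scaler is not None and self.numeric_columns:
            idx = [self.feature_columns.index(c) for c in self.numeric_columns]
            arr[:, idx] = self.scaler.transform(arr[:, idx])
        return arr


def fit_mlp(
    features: pd.DataFrame,
    y: np.ndarray,
    hyperparams: MlpHyperparams | None = None,
) -> MlpModel:
    """Fit the perceptron on an (already derived) feature table.

    ``features`` may be the raw predictor table (categoricals are one-hot
    encoded with fixed reference levels) or an already-encoded design
    frame.  Numeric columns are z-scored with statistics from this
    training data only.  Deterministic given ``random_state``.
    """
    hp = hyperparams or MlpHyperparams()
    if features.select_dtypes(include=["object", "category"]).shape[1]:
        X, encoding = encode_features(features)
    else:
        X, encoding = features.copy(), {}
    X = X.astype(float)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("non-finite values in feature matrix")
    numeric_cols = [c for c in X.columns if c in NUMERIC_FEATURES]
    arr = X.to_numpy()
    scaler = None
    if numeric_cols:
        idx = [list(X.columns).index(c) for c in numeric_cols]
        scaler = StandardScaler().fit(arr[:, idx])
        arr[:, idx] = scaler.transform(arr[:, idx])
    clf = MLPClassifier(
        hidden_layer_sizes=tuple(hp.hidden_layer_spec),
        activation=hp.activation,
        solver=hp.solver,
        alpha=hp.alpha,
        tol=hp.tol,
        learning_rate_init=hp.learning_rate_init,
        max_iter=hp.max_iter,
        random_state=hp.random_state,
    )
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(arr, np.asarray(y, int))
    converged = clf.n_iter_ < hp.max_iter
    return MlpModel(
        clf=clf,
        scaler=scaler,
        feature_columns=list(X.columns),
        numeric_columns=numeric_cols,
        encoding=encoding,
        converged=converged,
    )


def predict_mlp(model: MlpModel, features: pd.DataFrame) -> np.ndarray:
    """Positive-class (progressed-to-AD) probability per observation."""
    arr = model._design(features)
    proba = model.clf.predict_proba(arr)
    pos_idx = int(np.where(model.clf.classes_ == 1)[0][0])
    return proba[:, pos_idx]


def rank_mlp_features(
    model: MlpModel,
    feature_names: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Importance = sum of |first-layer weights| per input feature.

    The p-value is a one-sample t-test of the signed first-layer weights
    of that input against mean zero; with a single hidden unit the test
    is undefined and the p-value is reported missing (NaN).  Sorted by
    importance, descending, stable ties.
    """
    W = model.clf.coefs_[0]  # (n_features, n_hidden)
    names = feature_names if feature_names is not None else model.feature_columns
    if len(names) != W.shape[0]:
        raise ValueError("feature_names length does not match the network input size")
    importance = np.abs(W).sum(axis=1)
    if W.shape[1] >= 2:
        pvals = stats.ttest_1samp(W, popmean=0.0, axis=1).pvalue
    else:
        pvals = np.full(W.shape[0], np.nan)
    table = pd.DataFrame(
        {
            "feature": names,
            "importance": importance,
            "p_value": pvals,
            "significant": pd.Series(pvals < alpha).fillna(False).to_numpy(),
        }
    )
    table = table.sort_values("importance", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)
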