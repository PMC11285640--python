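"""Classification metric panel: confusion-matrix metrics, ROC/AUC with CI, model comparison.

The positive class throughout is progression to Alzheimer's disease
(outcome = 1).  AUC is the trapezoidal area under the empirical ROC
curve with midrank handling of score ties (equivalently, the normalized
Mann–Whitney U statistic); its confidence interval comes from a
stratified percentile bootstrap by default, with the Hanley–McNeil
asymptotic variance available as an alternative.  An AUC above 0.80 is
flagged as crossing the conventional clinical-relevance line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "EvaluationReport",
    "confusion_and_metrics",
    "auc_with_ci",
    "f1_consistency",
    "compare_models",
    "CLINICAL_RELEVANCE_AUC",
]

CLINICAL_RELEVANCE_AUC = 0.80


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


@dataclass
class EvaluationReport:
    """Threshold metrics plus (optionally) the AUC block for one model."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None
    precision: float | None   # positive class = progressed to AD
    recall: float | None      # sensitivity
    specificity: float | None
    f1: float | None
    per_class: dict = field(default_factory=dict)
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    roc_points: pd.DataFrame | None = None
    n: int = 0

    def as_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "per_class": self.per_class, "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None, "n": self.n,
        }
        return d


def _class_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    p = _safe_div(tp, tp + fp)
    r = _safe_div(tp, tp + fn)
    f1 = None if (p is None or r is None or (p + r) == 0) else 2 * p * r / (p + r)
    return {"precision": p, "recall": r, "f1": f1}


def confusion_and_metrics(y_true, y_pred_class) -> EvaluationReport:
    """Confusion matrix and the full threshold-metric panel.

    Per-class precision/recall/F1 are computed for both classes (the
    remained-MDD metrics are the positive-class metrics with the classes
    swapped).  Undefined ratios (zero denominators) are reported as
    ``None`` rather than propagating NaN.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred_class, int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred_class must be equal-length, non-empty")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    pos = _class_metrics(tp, fp, tn, fn)
    neg = _class_metrics(tn, fn, tp, fp)  # swap positive class
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_safe_div(tp + tn, tp + fp + tn + fn),
        precision=pos["precision"],
        recall=pos["recall"],
        specificity=_safe_div(tn, tn + fp),
        f1=pos["f1"],
        per_class={"progressed_AD": pos, "remained_MDD": neg},
        n=int(y_true.size),
    )


def _trapezoid_auc(y_true: np.ndarray, y_score: np.ndarray) -> tuple[float, pd.DataFrame]:
    fpr, tpr, _ = roc_curve(y_true, y_score, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr})


def auc_with_ci(
    y_true,
    y_score,
    method: str = "bootstrap",
    seed: int = 0,
    n_boot: int = 2000,
    conf_level: float = 0.95,
) -> EvaluationReport:
    """AUC with a confidence interval and the ROC curve points.

    ``method="bootstrap"``: stratified (within-class) resampling,
    percentile interval.  ``method="hanley"``: Hanley–McNeil asymptotic
    normal interval.  Score ties are handled by the midrank convention
    of the empirical ROC.
    """
    y_true = np.asarray(y_true, int)
    y_score = np.asarray(y_score, float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both outcome classes must be present to compute an AUC")
    auc, roc_points = _trapezoid_auc(y_true, y_score)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx1 = np.flatnonzero(y_true == 1)
        idx0 = np.flatnonzero(y_true == 0)
        stats_ = np.empty(n_boot)
        for b in range(n_boot):
            i1 = rng.choice(idx1, size=len(idx1), replace=True)
            i0 = rng.choice(idx0, size=len(idx0), replace=True)
            idx = np.concatenate([i1, i0])
            stats_[b], _ = _trapezoid_auc(y_true[idx], y_score[idx])
        lo, hi = np.quantile(stats_, [(1 - conf_level) / 2, 1 - (1 - conf_level) / 2])
    elif method == "hanley":
        n1, n0 = int((y_true == 1).sum()), int((y_true == 0).sum())
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (
            auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
        ) / (n1 * n0)
        from scipy.stats import norm

        z = norm.ppf(1 - (1 - conf_level) / 2)
        lo, hi = auc - z * np.sqrt(max(var, 0.0)), auc + z * np.sqrt(max(var, 0.0))
    else:
        raise ValueError("method must be 'bootstrap' or 'hanley'")

    return EvaluationReport(
        tp=0, fp=0, tn=0, fn=0, accuracy=None, precision=None, recall=None,
        specificity=None, f1=None, auc=auc,
        auc_ci=(float(max(lo, 0.0)), float(min(hi, 1.0))),
        roc_points=roc_points, n=int(y_true.size),
    )


def f1_consistency(precision: float, recall: float, decimals: int = 2) -> float | None:
    """Harmonic mean of precision and recall, rounded to report precision."""
    if precision + recall == 0:
        return None
    return round(2 * precision * recall / (precision + recall), decimals)


def compare_models(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Side-by-side metric table across models, Table-2-shaped.

    All reports must refer to the same test partition (checked by n).
    Models whose AUC crosses the 0.80 clinical-relevance line are
    flagged.
    """
    sizes = {name: r.n for name, r in reports.items()}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"reports computed on different test sets: {sizes}")
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "model": name,
                "precision_remained_MDD": r.per_class.get("remained_MDD", {}).get("precision"),
                "precision_progressed_AD": r.per_class.get("progressed_AD", {}).get("precision"),
                "recall_remained_MDD": r.per_class.get("remained_MDD", {}).get("recall"),
                "recall_progressed_AD": r.per_class.get("progressed_AD", {}).get("recall"),
                "f1_remained_MDD": r.per_class.get("remained_MDD", {}).get("f1"),
                "f1_progressed_AD": r.per_class.get("progressed_AD", {}).get("f1"),
                "accuracy": r.accuracy,
                "auc": r.auc,
                "auc_ci_low": r.auc_ci[0] if r.auc_ci else None,
                "auc_ci_high": r.auc_ci[1] if r.auc_ci else None,
                "clinically_relevant": (r.auc is not None and r.auc > CLINICAL_RELEVANCE_AUC),
            }
        )
    return pd.DataFrame(rows)
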