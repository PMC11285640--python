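"""From raw claims to the analysis table.

ICD code classification, outcome construction (MDD must strictly precede
AD at year resolution), random equal-size control sampling, derivation of
the nine-predictor feature set, and the group-comparison descriptive
table (chi-square for categoricals, two-sided t for numerics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_claims import (
    AGE_GROUPS,
    GENDERS,
    HPSA_LEVELS,
    RACES,
    RURAL_URBAN,
    PatientRecord,
)

__all__ = [
    "CodeRegistry",
    "DEFAULT_REGISTRY",
    "EXTENDED_REGISTRY",
    "CohortRow",
    "OutcomeSummary",
    "classify_code",
    "build_outcome",
    "sample_controls",
    "derive_features",
    "build_cohort_table",
    "descriptive_table",
    "encode_features",
    "CATEGORICAL_LEVELS",
    "NUMERIC_FEATURES",
    "FEATURE_COLUMNS",
    "COHORT_COLUMNS",
]


@dataclass(frozen=True)
class CodeRegistry:
    """Diagnosis-code families used to classify claims.

    MDD families are wildcard prefixes (a code matches if it starts with
    the prefix); AD codes are exact.  The default registry holds single-
    episode depression only (ICD-9 296.2X, ICD-10 F32.X); the extended
    registry adds the recurrent families (296.3X, F33.X) for analyses that
    want the broader clinical-depression definition.  The two are never
    merged silently.
    """

    mdd_icd9_prefixes: tuple[str, ...] = ("296.2",)
    mdd_icd10_prefixes: tuple[str, ...] = ("F32",)
    ad_icd9_codes: tuple[str, ...] = ("331.0",)
    ad_icd10_codes: tuple[str, ...] = ("G30.0", "G30.1", "G30.8", "G30.9")


DEFAULT_REGISTRY = CodeRegistry()
EXTENDED_REGISTRY = CodeRegistry(
    mdd_icd9_prefixes=("296.2", "296.3"),
    mdd_icd10_prefixes=("F32", "F33"),
)


def classify_code(code_system: str, code: str, registry: CodeRegistry = DEFAULT_REGISTRY) -> str:
    """Classify a diagnosis code as ``"MDD"``, ``"AD"`` or ``"OTHER"``."""
    if not code:
        raise ValueError("empty diagnosis code")
    if code_system == "ICD9":
        if any(code.startswith(p) for p in registry.mdd_icd9_prefixes):
            return "MDD"
        if code in registry.ad_icd9_codes:
            return "AD"
        return "OTHER"
    if code_system == "ICD10":
        if any(code.startswith(p) for p in registry.mdd_icd10_prefixes):
            return "MDD"
        if code in registry.ad_icd10_codes:
            return "AD"
        return "OTHER"
    raise ValueError(f"unknown code system {code_system!r}; expected 'ICD9' or 'ICD10'")


@dataclass
class OutcomeSummary:
    """Bookkeeping of the outcome-construction pass."""

    n_progressed: int = 0
    n_remained: int = 0
    n_excluded_ad_precedes: int = 0
    n_excluded_ad_without_mdd: int = 0
    n_dropped_no_claims: int = 0


def _first_years(record: PatientRecord, registry: CodeRegistry) -> tuple[int | None, int | None]:
    first_mdd = first_ad = None
    for claim in record.claims:
        cls = classify_code(claim.code_system, claim.code, registry)
        if cls == "MDD" and (first_mdd is None or claim.year < first_mdd):
            first_mdd = claim.year
        elif cls == "AD" and (first_ad is None or claim.year < first_ad):
            first_ad = claim.year
    return first_mdd, first_ad


def build_outcome(
    records: list[PatientRecord],
    registry: CodeRegistry = DEFAULT_REGISTRY,
) -> tuple[list[tuple[PatientRecord, int]], OutcomeSummary]:
    """Label each record 1 (progressed to AD) or 0 (remained MDD).

    A progressor's first MDD-coded claim year must strictly precede the
    first AD-coded year.  Records where AD does not follow MDD (ties at
    year resolution included, since precedence cannot be established) are
    excluded and counted, as are AD-only records and claimless records.
    """
    labeled: list[tuple[PatientRecord, int]] = []
    summary = OutcomeSummary()
    for record in records:
        if not record.claims:
            summary.n_dropped_no_claims += 1
            continue
        first_mdd, first_ad = _first_years(record, registry)
        if first_mdd is None:
            if first_ad is not None:
                summary.n_excluded_ad_without_mdd += 1
            # neither MDD nor AD: not in the study population
            continue
        if first_ad is None:
            labeled.append((record, 0))
            summary.n_remained += 1
        elif first_mdd < first_ad:
            labeled.append((record, 1))
            summary.n_progressed += 1
        else:
            summary.n_excluded_ad_precedes += 1
    if summary.n_dropped_no_claims:
        warnings.warn(
            f"dropped {summary.n_dropped_no_claims} record(s) with no claims",
            stacklevel=2,
        )
    return labeled, summary


def sample_controls(candidates: list, n: int, seed: int) -> list:
    """Simple random sample of ``n`` candidates without replacement."""
    if len(candidates) < n:
        raise ValueError(
            f"insufficient control candidates: need {n}, have {len(candidates)} "
            f"(shortfall {n - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


@dataclass
class CohortRow:
    """Analysis-ready feature vector plus binary outcome for one patient."""

    patient_id: str
    age_group: str
    gender: str
    race: str
    rural_urban: str
    hpsa: str
    comorbidity: str       # "none" | "one-or-more"
    follow_up: str         # "no-follow-up" | "at-least-two-visits"
    utilization_days: int  # total days over claims at/after first MDD year
    mdd_claim_count: int
    outcome: int = field(default=0)  # 0 remained MDD, 1 progressed to AD


def derive_features(
    record: PatientRecord,
    registry: CodeRegistry = DEFAULT_REGISTRY,
    outcome: int = 0,
) -> CohortRow:
    """Derive the nine-predictor row for one patient.

    Utilization days sum over all claims from the first MDD year onward;
    comorbidity means any non-MDD/non-AD claim anywhere in the record;
    follow-up means at least two MDD-coded claims (visits).
    """
    classes = [classify_code(c.code_system, c.code, registry) for c in record.claims]
    mdd_years = [c.year for c, k in zip(record.claims, classes) if k == "MDD"]
    if not mdd_years:
        raise ValueError(f"record {record.patient_id} has no MDD-classified claim")
    first_mdd = min(mdd_years)
    utilization = sum(c.utilization_days for c in record.claims if c.year >= first_mdd)
    mdd_count = len(mdd_years)
    comorbidity = "one-or-more" if any(k == "OTHER" for k in classes) else "none"
    follow_up = "at-least-two-visits" if mdd_count >= 2 else "no-follow-up"
    return CohortRow(
        patient_id=record.patient_id,
        age_group=record.age_group,
        gender=record.gender,
        race=record.race,
        rural_urban=record.rural_urban,
        hpsa=record.hpsa,
        comorbidity=comorbidity,
        follow_up=follow_up,
        utilization_days=int(utilization),
        mdd_claim_count=int(mdd_count),
        outcome=int(outcome),
    )


COHORT_COLUMNS = [
    "patient_id",
    "age_group",
    "gender",
    "race",
    "rural_urban",
    "hpsa",
    "comorbidity",
    "follow_up",
    "utilization_days",
    "mdd_claim_count",
    "outcome",
]

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": AGE_GROUPS,
    "gender": GENDERS,
    "race": RACES,
    "rural_urban": RURAL_URBAN,
    "hpsa": HPSA_LEVELS,
    "comorbidity": ("none", "one-or-more"),
    "follow_up": ("no-follow-up", "at-least-two-visits"),
}
NUMERIC_FEATURES = ("utilization_days", "mdd_claim_count")
FEATURE_COLUMNS = list(CATEGORICAL_LEVELS) + list(NUMERIC_FEATURES)


def build_cohort_table(
    labeled: list[tuple[PatientRecord, int]],
    registry: CodeRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Assemble the analysis table (documented column order)."""
    rows = [derive_features(rec, registry, outcome=y) for rec, y in labeled]
    df = pd.DataFrame([vars(r) for r in rows])
    return df[COHORT_COLUMNS]


def descriptive_table(
    cohort: pd.DataFrame,
    continuity_correction: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group descriptives with significance tests.

    Categorical predictors get within-group counts and percentages and a
    chi-square test of independence (no continuity correction by
    default); numeric predictors get mean ± SD and a two-sided
    independent-sample t-test.  Returns a long-format table; one p-value
    per variable, repeated on its level rows.
    """
    g0 = cohort[cohort["outcome"] == 0]
    g1 = cohort[cohort["outcome"] == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both outcome groups must be non-empty")
    out_rows = []
    for var, levels in CATEGORICAL_LEVELS.items():
        counts0 = g0[var].value_counts()
        counts1 = g1[var].value_counts()
        table = np.array(
            [[counts0.get(lv, 0) for lv in levels], [counts1.get(lv, 0) for lv in levels]]
        )
        nonzero = table.sum(axis=0) > 0
        note = ""
        if nonzero.sum() < 2:
            p = np.nan
            note = "chi-square skipped: single observed level"
        else:
            sub = table[:, nonzero]
            if sub.shape[1] == 2 and continuity_correction:
                _, p, _, _ = stats.chi2_contingency(sub, correction=True)
            else:
                _, p, _, _ = stats.chi2_contingency(sub, correction=False)
        for j, lv in enumerate(levels):
            out_rows.append(
                {
                    "variable": var,
                    "level": lv,
                    "n_remained": int(table[0, j]),
                    "pct_remained": round(100.0 * table[0, j] / len(g0), 2),
                    "n_progressed": int(table[1, j]),
                    "pct_progressed": round(100.0 * table[1, j] / len(g1), 2),
                    "mean_remained": np.nan,
                    "sd_remained": np.nan,
                    "mean_progressed": np.nan,
                    "sd_progressed": np.nan,
                    "test": "chi-square",
                    "p_value": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                    "note": note,
                }
            )
    for var in NUMERIC_FEATURES:
        x0 = g0[var].to_numpy(float)
        x1 = g1[var].to_numpy(float)
        t_res = stats.ttest_ind(x0, x1)
        out_rows.append(
            {
                "variable": var,
                "level": "",
                "n_remained": len(g0),
                "pct_remained": np.nan,
                "n_progressed": len(g1),
                "pct_progressed": np.nan,
                "mean_remained": round(float(np.mean(x0)), 2),
                "sd_remained": round(float(np.std(x0, ddof=1)), 2),
                "mean_progressed": round(float(np.mean(x1)), 2),
                "sd_progressed": round(float(np.std(x1, ddof=1)), 2),
                "test": "t-test",
                "p_value": float(t_res.pvalue),
                "significant": bool(t_res.pvalue < alpha),
                "note": "",
            }
        )
    return pd.DataFrame(out_rows)


def render_descriptive_table(table: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`descriptive_table` output."""
    lines = []
    lines.append(f"{'Predictor':<28}{'Remained MDD':>20}{'Progressed AD':>20}")
    for var, grp in table.groupby("variable", sort=False):
        star = "*" if grp["significant"].iloc[0] else ""
        lines.append(f"{var}{star}")
        for _, row in grp.iterrows():
            if row["test"] == "chi-square":
                left = f"{row['n_remained']} ({row['pct_remained']:.2f}%)"
                right = f"{row['n_progressed']} ({row['pct_progressed']:.2f}%)"
                lines.append(f"  {row['level']:<26}{left:>20}{right:>20}")
            else:
                left = f"{row['mean_remained']:.2f} ± {row['sd_remained']:.2f}"
                right = f"{row['mean_progressed']:.2f} ± {row['sd_progressed']:.2f}"
                lines.append(f"  {'mean ± sd':<26}{left:>20}{right:>20}")
    return "\n".join(lines)


def encode_features(
    df: pd.DataFrame,
    drop_first: bool = True,
    feature_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One-hot encode the predictor set with fixed reference levels.

    Categorical columns expand into indicator columns ``var=level`` for
    every non-reference level of the documented vocabulary (the first
    level is the reference when ``drop_first``); unseen values map to the
    reference (all indicators zero) with a warning.  Numeric columns pass
    through as float.  Returns the design frame and the encoding map.
    """
    cols = feature_columns if feature_columns is not None else FEATURE_COLUMNS
    pieces = {}
    encoding: dict[str, dict] = {}
    for col in cols:
        if col in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[col]
            values = df[col].astype(object)
            unseen = ~values.isin(levels) & values.notna()
            if unseen.any():
                warnings.warn(
                    f"{int(unseen.sum())} value(s) of {col!r} outside the documented "
                    f"levels mapped to the reference level {levels[0]!r}",
                    stacklevel=2,
                )
            keep = levels[1:] if drop_first else levels
            for lv in keep:
                pieces[f"{col}={lv}"] = (values == lv).astype(float).to_numpy()
            encoding[col] = {"levels": list(levels), "reference": levels[0] if drop_first else None}
        else:
            pieces[col] = df[col].astype(float).to_numpy()
            encoding[col] = {"numeric": True}
    return pd.DataFrame(pieces, index=df.index), encoding
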