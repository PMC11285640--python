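"""Seeded synthetic Medicare-style claims cohorts with confounded longitudinal structure.

Generates two patient groups — those who remain with major depressive
disorder (MDD) and those who progress to Alzheimer's disease (AD) — as
year-resolution ICD-coded claim streams over a configurable window
(default 2012–2019).  The generative mechanism is a discrete-time
logistic-hazard process:

* ``Z_t`` — a binary time-varying comorbidity burden, persistent over time
  and elevated by past MDD exposure (``Z_t ← E_{t-1}``);
* ``E_t`` — the yearly MDD-claim exposure indicator, drawn conditional on
  ``E_{t-1}`` and ``Z_{t-1}`` (``confounding_strength`` scales the
  ``Z → E`` arrow); every patient is diagnosed at baseline (``E_0 = 1``);
* progression hazard from year 1 onward depends on cumulative exposure
  (``exposure_effect``), the current comorbidity burden, baseline age band,
  a latent standard-normal frailty ``U`` (``latent_effect``) that is never
  exported to the analysis table, and a balanced non-linear interaction of
  two demographics (``nonlinear_effect``) that a linear model cannot
  represent but a flexible learner can.

Z is therefore a classic time-varying confounder: it lies on the causal
pathway (affected by past exposure) while also driving future exposure and
the outcome, which is exactly the structure stabilized inverse-probability
weighting is designed to handle.

ICD coding follows the US claims convention for the window: ICD-9-CM for
years up to 2015, ICD-10-CM from 2016 on.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PatientRecord",
    "Claim",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_population",
    "inject_missingness",
    "AGE_GROUPS",
    "GENDERS",
    "RACES",
    "RURAL_URBAN",
    "HPSA_LEVELS",
    "DEFAULT_PREVALENCES",
]

# Fixed category vocabularies for the §-style predictor set.
AGE_GROUPS = ("<65", "65-69", "70-74", "75-79", "80-84", ">84")
GENDERS = ("male", "female")
RACES = ("white", "black", "other")
RURAL_URBAN = ("rural", "urban")
HPSA_LEVELS = ("none", "whole", "partly")

ICD9_MDD_CODES = ("296.20", "296.21", "296.22", "296.23")
ICD10_MDD_CODES = ("F32.0", "F32.1", "F32.2", "F32.9")
ICD9_AD_CODE = "331.0"
ICD10_AD_CODES = ("G30.0", "G30.1", "G30.8", "G30.9")
ICD9_COMORBID_CODES = ("401.9", "250.00", "272.4")
ICD10_COMORBID_CODES = ("I10", "E11.9", "E78.5")

ICD10_FIRST_YEAR = 2016  # ICD-9-CM through 2015, ICD-10-CM from 2016

# Pooled marginal frequencies of the published descriptive table
# (both study arms combined, N = 564), so synthetic descriptives have
# face validity against the real-cohort characteristics.
DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "age_group": {
        "<65": 149 / 564,
        "65-69": 47 / 564,
        "70-74": 50 / 564,
        "75-79": 166 / 564,
        "80-84": 90 / 564,
        ">84": 62 / 564,
    },
    "gender": {"male": 211 / 564, "female": 353 / 564},
    "race": {"white": 486 / 564, "black": 56 / 564, "other": 22 / 564},
    "rural_urban": {"rural": 437 / 564, "urban": 127 / 564},
    "hpsa": {"none": 62 / 564, "whole": 167 / 564, "partly": 335 / 564},
}

_CATEGORY_ORDER = {
    "age_group": AGE_GROUPS,
    "gender": GENDERS,
    "race": RACES,
    "rural_urban": RURAL_URBAN,
    "hpsa": HPSA_LEVELS,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class Claim:
    """One year-resolution diagnosis claim."""

    year: int
    code_system: str  # "ICD9" | "ICD10"
    code: str
    utilization_days: int


@dataclass
class PatientRecord:
    """A patient's demographics, county attributes and claim history."""

    patient_id: str
    age_group: str
    gender: str
    race: str
    rural_urban: str
    hpsa: str
    claims: list[Claim] = field(default_factory=list)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    The structural coefficients below the first block are on the logit
    scale of the yearly hazards; their defaults were chosen once to give a
    realistically sparse claim stream (mean MDD claim count near 2, total
    utilization near 10 days) and a cumulative progression risk around 30%
    over the 8-year window.
    """

    n_per_group: int = 282
    start_year: int = 2012
    end_year: int = 2019
    confounding_strength: float = 1.0  # Z_{t-1} -> E_t arrow
    exposure_effect: float = 0.35      # cumulative E -> progression hazard
    latent_effect: float = 0.8         # latent frailty U -> hazard
    missing_rate: float = 0.0
    seed: int = 0
    covariate_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PREVALENCES.items()}
    )
    # secondary structural coefficients (logit scale)
    nonlinear_effect: float = 1.0        # balanced interaction -> hazard
    covariate_outcome_effect: float = 0.8  # Z_t -> hazard (confounder arrow)
    exposure_persistence: float = 0.8    # E_{t-1} -> E_t
    comorbidity_persistence: float = 1.0  # Z_{t-1} -> Z_t
    comorbidity_exposure_feedback: float = 0.8  # E_{t-1} -> Z_t
    baseline_exposure_logit: float = -2.2
    baseline_comorbidity_logit: float = -1.2
    baseline_hazard_logit: float = -3.2
    age_effect: float = 0.25             # per age-band index -> hazard
    # When True (cohort realism), claims and exposure stop at the
    # progression year — follow-up ends at the event.  Monte-Carlo designs
    # that regress an end-of-window outcome on cumulative exposure need
    # the untruncated history (False), otherwise truncation induces a
    # spurious negative exposure–outcome association.
    truncate_at_event: bool = True

    def validate(self) -> None:
        if not (isinstance(self.n_per_group, (int, np.integer)) and self.n_per_group > 0):
            raise ConfigurationError("n_per_group must be a positive integer")
        if self.start_year >= self.end_year:
            raise ConfigurationError("start_year must be strictly before end_year")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")
        for name, probs in self.covariate_prevalences.items():
            if name not in _CATEGORY_ORDER:
                raise ConfigurationError(f"covariate_prevalences: unknown predictor {name!r}")
            levels = _CATEGORY_ORDER[name]
            if set(probs) != set(levels):
                raise ConfigurationError(
                    f"covariate_prevalences[{name!r}] must give a probability for "
                    f"each of {levels}"
                )
            total = float(sum(probs.values()))
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"covariate_prevalences[{name!r}] probabilities sum to {total}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(
                    f"covariate_prevalences[{name!r}] contains a negative probability"
                )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float], levels: tuple, n: int) -> np.ndarray:
    p = np.array([probs[level] for level in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(len(levels), size=n, p=p)


def _simulate_latent(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator,
    exposure_mode: str = "confounded",
    randomized_rate: float | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized draw of the latent panel process for ``n`` patients.

    Returns arrays over patients × years: exposure ``E``, comorbidity
    burden ``Z``, per-year event hazard draws, the progression year index
    (−1 for non-progressors), demographics as level indices, and the
    latent frailty ``U``.
    """
    T = config.n_years
    demo = {
        name: _draw_categorical(rng, config.covariate_prevalences[name], _CATEGORY_ORDER[name], n)
        for name in _CATEGORY_ORDER
    }
    U = rng.standard_normal(n)

    # balanced ±1 interaction of gender and HPSA-partly: invisible to
    # main-effects-only models, learnable by trees / networks
    xor = (demo["gender"] == 1) ^ (demo["hpsa"] == 2)
    nl = np.where(xor, 1.0, -1.0) * 0.5

    E = np.zeros((n, T), dtype=np.int8)
    Z = np.zeros((n, T), dtype=np.int8)
    E[:, 0] = 1  # cohort entry = first MDD diagnosis at baseline
    Z[:, 0] = rng.random(n) < _expit(np.full(n, config.baseline_comorbidity_logit))

    cum_e = E[:, 0].astype(float)
    event_t = np.full(n, -1, dtype=int)
    alive = np.ones(n, dtype=bool)

    for t in range(1, T):
        z_logit = (
            config.baseline_comorbidity_logit
            + config.comorbidity_persistence * Z[:, t - 1]
            + config.comorbidity_exposure_feedback * E[:, t - 1]
        )
        Z[:, t] = rng.random(n) < _expit(z_logit)

        if exposure_mode == "randomized":
            rate = 0.15 if randomized_rate is None else randomized_rate
            E[:, t] = rng.random(n) < rate
        else:
            e_logit = (
                config.baseline_exposure_logit
                + config.confounding_strength * Z[:, t - 1]
                + config.exposure_persistence * E[:, t - 1]
            )
            E[:, t] = rng.random(n) < _expit(e_logit)
        cum_e = cum_e + E[:, t]

        h_logit = (
            config.baseline_hazard_logit
            + config.exposure_effect * cum_e
            + config.covariate_outcome_effect * Z[:, t]
            + config.latent_effect * U
            + config.age_effect * demo["age_group"]
            + config.nonlinear_effect * nl
        )
        fire = (rng.random(n) < _expit(h_logit)) & alive
        event_t[fire] = t
        alive &= ~fire

    if config.truncate_at_event:
        # follow-up ends at the progression year: no exposure/claims after it
        for i in np.flatnonzero(event_t >= 0):
            E[i, event_t[i] + 1 :] = 0
            Z[i, event_t[i] + 1 :] = 0

    return {"E": E, "Z": Z, "event_t": event_t, "U": U, "demo": demo}


def _records_from_latent(
    config: SimulationConfig,
    latent: dict[str, np.ndarray],
    rng: np.random.Generator,
    id_offset: int = 0,
) -> list[PatientRecord]:
    n, T = latent["E"].shape
    years = np.arange(config.start_year, config.end_year + 1)
    demo = latent["demo"]
    records: list[PatientRecord] = []
    for i in range(n):
        claims: list[Claim] = []
        if config.truncate_at_event and latent["event_t"][i] >= 0:
            stop = latent["event_t"][i]
        else:
            stop = T - 1
        for t in range(stop + 1):
            year = int(years[t])
            icd9 = year < ICD10_FIRST_YEAR
            system = "ICD9" if icd9 else "ICD10"
            if latent["E"][i, t]:
                code = (ICD9_MDD_CODES if icd9 else ICD10_MDD_CODES)[rng.integers(4)]
                days = int(rng.poisson(3 + 2 * latent["Z"][i, t]) + 1)
                claims.append(Claim(year, system, code, days))
            if latent["Z"][i, t]:
                code = (ICD9_COMORBID_CODES if icd9 else ICD10_COMORBID_CODES)[rng.integers(3)]
                claims.append(Claim(year, system, code, int(rng.poisson(2))))
            if latent["event_t"][i] == t:
                code = ICD9_AD_CODE if icd9 else ICD10_AD_CODES[rng.integers(4)]
                claims.append(Claim(year, system, code, int(rng.poisson(5) + 1)))
        claims.sort(key=lambda c: c.year)
        records.append(
            PatientRecord(
                patient_id=f"P{id_offset + i:07d}",
                age_group=AGE_GROUPS[demo["age_group"][i]],
                gender=GENDERS[demo["gender"][i]],
                race=RACES[demo["race"][i]],
                rural_urban=RURAL_URBAN[demo["rural_urban"][i]],
                hpsa=HPSA_LEVELS[demo["hpsa"][i]],
                claims=claims,
            )
        )
    return records


def simulate_population(
    config: SimulationConfig,
    n_patients: int,
    rng: np.random.Generator | None = None,
    exposure_mode: str = "confounded",
    randomized_rate: float | None = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Simulate ``n_patients`` without conditioning on the outcome.

    Returns the claim records together with a ground-truth table
    (progression indicator, event year, cumulative exposure, latent
    frailty) for Monte-Carlo studies.  ``exposure_mode="randomized"``
    severs the confounder→exposure arrow by drawing post-baseline exposure
    as independent Bernoulli draws, which identifies the marginal exposure
    effect by design.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    latent = _simulate_latent(config, n_patients, rng, exposure_mode, randomized_rate)
    records = _records_from_latent(config, latent, rng)
    truth = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "progressed": latent["event_t"] >= 0,
            "event_year": np.where(
                latent["event_t"] >= 0, config.start_year + latent["event_t"], -1
            ),
            "cum_exposure": latent["E"].sum(axis=1),
            "latent_u": latent["U"],
        }
    )
    return records, truth


def simulate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Simulate a balanced case/control cohort of ``2 × n_per_group`` patients.

    Patients are simulated in batches from the natural (unconditioned)
    progression process until ``n_per_group`` progressors and
    ``n_per_group`` never-progressors have accrued, then the first
    ``n_per_group`` of each group in simulation order are returned
    (cases first, then controls).  Bit-identical for identical
    ``(config, seed)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cases: list[PatientRecord] = []
    controls: list[PatientRecord] = []
    offset = 0
    batch = max(2048, 4 * config.n_per_group)
    max_draws = 400 * config.n_per_group + 100_000
    while len(cases) < config.n_per_group or len(controls) < config.n_per_group:
        if offset > max_draws:
            raise RuntimeError(
                "cohort accumulation did not reach the requested group sizes; "
                "the configured hazards leave one group too rare"
            )
        latent = _simulate_latent(config, batch, rng)
        records = _records_from_latent(config, latent, rng, id_offset=offset)
        offset += batch
        for rec, et in zip(records, latent["event_t"]):
            if et >= 0:
                if len(cases) < config.n_per_group:
                    cases.append(rec)
            elif len(controls) < config.n_per_group:
                controls.append(rec)
    return cases + controls


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed: int,
    outcome_col: str = "outcome",
    id_cols: tuple[str, ...] = ("patient_id",),
) -> pd.DataFrame:
    """Mask each predictor cell independently with probability ``rate``.

    The outcome and identifier columns are never touched.  Masked cells
    become NaN (object columns become None via NaN).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    predictor_cols = [c for c in table.columns if c != outcome_col and c not in id_cols]
    mask = rng.random((len(table), len(predictor_cols))) < rate
    for j, col in enumerate(predictor_cols):
        col_mask = mask[:, j]
        if col_mask.any():
            if out[col].dtype.kind in "iub":
                out[col] = out[col].astype(float)
            out.loc[out.index[col_mask], col] = np.nan
    return out
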