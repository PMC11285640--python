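import pytest

from mdd2ad import (
    SimulationConfig,
    build_cohort_table,
    build_outcome,
    simulate_cohort,
    split_cohort,
)
from mdd2ad.causal_weights import build_panel, compute_iptw, fit_exposure_models
from mdd2ad.ensemble_ipm import fit_ipm


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_per_group=60, seed=1234)


@pytest.fixture(scope="session")
def cohort_records(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def labeled_records(cohort_records):
    labeled, _ = build_outcome(cohort_records)
    return labeled


@pytest.fixture(scope="session")
def cohort_table(labeled_records):
    return build_cohort_table(labeled_records)


@pytest.fixture(scope="session")
def fitted_bundle(sim_config, labeled_records, cohort_table):
    """Train/test split, stabilized weights, and a fitted ensemble."""
    train, test = split_cohort(cohort_table, seed=77)
    train_ids = set(train["patient_id"])
    train_records = [r for r, _ in labeled_records if r.patient_id in train_ids]
    panel = build_panel(train_records, sim_config.start_year, sim_config.end_year)
    models = fit_exposure_models(panel)
    weights = compute_iptw(panel, models)
    w_tr = (
        weights.set_index("patient_id")["weight"]
        .reindex(train["patient_id"])
        .to_numpy(float)
    )
    ipm = fit_ipm(train, train["outcome"].to_numpy(int), w_tr)
    return {
        "train": train,
        "test": test,
        "panel": panel,
        "exposure_models": models,
        "weights": weights,
        "w_train": w_tr,
        "ipm": ipm,
    }
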