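"""ICD classification, outcome precedence, feature derivation, descriptives."""

import numpy as np
import pandas as pd
import pytest

from mdd2ad import (
    DEFAULT_REGISTRY,
    EXTENDED_REGISTRY,
    build_outcome,
    classify_code,
    derive_features,
    descriptive_table,
    sample_controls,
)
from mdd2ad.synthetic_claims import Claim, PatientRecord


def _patient(claims, pid="p1"):
    return PatientRecord(
        patient_id=pid, age_group="75-79", gender="female", race="white",
        rural_urban="rural", hpsa="partly",
        claims=sorted(claims, key=lambda c: c.year),
    )


@pytest.mark.parametrize(
    "system,code,expected",
    [
        ("ICD10", "G30.9", "AD"),
        ("ICD10", "G30.0", "AD"),
        ("ICD9", "331.0", "AD"),
        ("ICD9", "296.21", "MDD"),
        ("ICD9", "296.2", "MDD"),
        ("ICD10", "F32.9", "MDD"),
        ("ICD10", "F33.1", "OTHER"),  # recurrent family excluded by default
        ("ICD9", "296.31", "OTHER"),
        ("ICD9", "401.9", "OTHER"),
        ("ICD10", "G30.2", "OTHER"),  # AD codes are exact, not a prefix family
        ("ICD9", "331.00", "OTHER"),
    ],
)
def test_classify_code_default_registry(system, code, expected):
    assert classify_code(system, code) == expected


def test_extended_registry_adds_recurrent_depression():
    assert classify_code("ICD10", "F33.1", EXTENDED_REGISTRY) == "MDD"
    assert classify_code("ICD9", "296.31", EXTENDED_REGISTRY) == "MDD"
    # default registry is never silently merged
    assert classify_code("ICD10", "F33.1", DEFAULT_REGISTRY) == "OTHER"


def test_classify_code_rejects_bad_inputs():
    with pytest.raises(ValueError):
        classify_code("ICD11", "foo")
    with pytest.raises(ValueError):
        classify_code("ICD9", "")


class TestBuildOutcome:
    def test_mdd_then_ad_is_progressor(self):
        rec = _patient([Claim(2013, "ICD9", "296.21", 1), Claim(2017, "ICD10", "G30.9", 2)])
        labeled, summary = build_outcome([rec])
        assert labeled == [(rec, 1)]
        assert summary.n_progressed == 1

    def test_ad_before_mdd_is_excluded(self):
        rec = _patient([Claim(2013, "ICD9", "331.0", 1), Claim(2015, "ICD9", "296.22", 1)])
        labeled, summary = build_outcome([rec])
        assert labeled == []
        assert summary.n_excluded_ad_precedes == 1

    def test_same_year_tie_is_excluded(self):
        rec = _patient([Claim(2014, "ICD9", "296.21", 1), Claim(2014, "ICD9", "331.0", 1)])
        labeled, summary = build_outcome([rec])
        assert labeled == []
        assert summary.n_excluded_ad_precedes == 1

    def test_mdd_only_is_control_candidate(self):
        rec = _patient([Claim(2014, "ICD9", "296.20", 1)])
        labeled, summary = build_outcome([rec])
        assert labeled == [(rec, 0)]
        assert summary.n_remained == 1

    def test_claimless_record_dropped_with_count(self):
        with pytest.warns(UserWarning):
            labeled, summary = build_outcome([_patient([])])
        assert labeled == [] and summary.n_dropped_no_claims == 1

    def test_label_invariant_to_claim_order(self):
        claims = [
            Claim(2013, "ICD9", "296.21", 1),
            Claim(2012, "ICD9", "401.9", 2),
            Claim(2017, "ICD10", "G30.9", 2),
            Claim(2016, "ICD10", "F32.0", 1),
        ]
        rng = np.random.default_rng(0)
        labels = set()
        for _ in range(6):
            perm = [claims[i] for i in rng.permutation(len(claims))]
            rec = PatientRecord("p", "<65", "male", "white", "rural", "none", perm)
            labeled, _ = build_outcome([rec])
            labels.add(labeled[0][1])
        assert labels == {1}


class TestSampleControls:
    def test_full_sample_returns_everything(self):
        cands = list(range(10))
        assert sorted(sample_controls(cands, 10, seed=1)) == cands

    def test_seed_reproducibility(self):
        cands = list(range(500))
        assert sample_controls(cands, 50, 9) == sample_controls(cands, 50, 9)

    def test_shortfall_error(self):
        with pytest.raises(ValueError, match="shortfall"):
            sample_controls([1, 2], 3, seed=0)

    def test_inclusion_frequencies_uniform(self):
        # 1,000 reseeded draws of 282 from 5,000: per-candidate inclusion
        # frequency should behave binomially around 282/5000
        n_pop, n_draw, n_rep = 5000, 282, 1000
        counts = np.zeros(n_pop)
        for s in range(n_rep):
            for i in sample_controls(list(range(n_pop)), n_draw, seed=s):
                counts[i] += 1
        p = n_draw / n_pop
        se = np.sqrt(p * (1 - p) / n_rep)
        within = np.abs(counts / n_rep - p) <= 3 * se
        assert counts.sum() == n_draw * n_rep
        assert within.mean() > 0.99  # ~99.7% expected under the binomial


class TestDeriveFeatures:
    def test_hand_computed_example(self):
        rec = _patient(
            [
                Claim(2013, "ICD9", "296.21", 3),
                Claim(2012, "ICD9", "401.9", 5),   # pre-MDD: excluded from utilization
                Claim(2015, "ICD9", "296.22", 4),
            ]
        )
        row = derive_features(rec)
        assert row.utilization_days == 7
        assert row.comorbidity == "one-or-more"
        assert row.mdd_claim_count == 2
        assert row.follow_up == "at-least-two-visits"

    def test_single_mdd_claim(self):
        row = derive_features(_patient([Claim(2014, "ICD9", "296.20", 2)]))
        assert row.follow_up == "no-follow-up"
        assert row.comorbidity == "none"
        assert row.mdd_claim_count == 1
        assert row.utilization_days == 2

    def test_no_mdd_claim_errors(self):
        with pytest.raises(ValueError, match="no MDD"):
            derive_features(_patient([Claim(2014, "ICD9", "401.9", 2)]))

    def test_idempotent_and_pure(self):
        rec = _patient([Claim(2013, "ICD9", "296.21", 3), Claim(2015, "ICD9", "401.9", 1)])
        before = [(c.year, c.code, c.utilization_days) for c in rec.claims]
        r1, r2 = derive_features(rec), derive_features(rec)
        assert r1 == r2
        assert [(c.year, c.code, c.utilization_days) for c in rec.claims] == before


def _printed_cohort():
    """Cohort with the published gender and rural-urban group counts."""
    rows = []

    def add(n, outcome, gender, rural):
        rows.extend(
            {
                "patient_id": f"g{outcome}{gender}{rural}{i}",
                "age_group": "75-79", "gender": gender, "race": "white",
                "rural_urban": rural, "hpsa": "partly",
                "comorbidity": "one-or-more", "follow_up": "no-follow-up",
                "utilization_days": 5, "mdd_claim_count": 2, "outcome": outcome,
            }
            for i in range(n)
        )

    # remained MDD: 115 male / 167 female; 233 rural / 49 urban
    add(115 - 49, 0, "male", "rural")
    add(49, 0, "male", "urban")
    add(167, 0, "female", "rural")
    # progressed: 96 male / 186 female; 204 rural / 78 urban
    add(96 - 78, 1, "male", "rural")
    add(78, 1, "male", "urban")
    add(186, 1, "female", "rural")
    return pd.DataFrame(rows)


class TestDescriptiveTable:
    def test_within_group_percentages_match_published_arithmetic(self):
        table = descriptive_table(_printed_cohort())
        gender = table[table["variable"] == "gender"].set_index("level")
        assert gender.loc["female", "pct_remained"] == pytest.approx(59.22, abs=0.005)
        assert gender.loc["female", "pct_progressed"] == pytest.approx(65.96, abs=0.005)
        ru = table[table["variable"] == "rural_urban"].set_index("level")
        assert ru.loc["rural", "pct_remained"] == pytest.approx(82.62, abs=0.005)
        assert ru.loc["rural", "pct_progressed"] == pytest.approx(72.34, abs=0.005)

    def test_rural_urban_significant_gender_not(self):
        table = descriptive_table(_printed_cohort())
        ru = table[table["variable"] == "rural_urban"]
        assert ru["p_value"].iloc[0] < 0.05 and ru["significant"].all()
        gender = table[table["variable"] == "gender"]
        assert gender["p_value"].iloc[0] > 0.05

    def test_percentages_sum_to_100_per_variable(self, cohort_table):
        table = descriptive_table(cohort_table)
        cat = table[table["test"] == "chi-square"]
        for _, grp in cat.groupby("variable"):
            assert grp["pct_remained"].sum() == pytest.approx(100, abs=0.05)
            assert grp["pct_progressed"].sum() == pytest.approx(100, abs=0.05)

    def test_identical_groups_give_p_one(self):
        half = _printed_cohort()
        half = half[half["outcome"] == 0].copy()
        dup = half.copy()
        dup["outcome"] = 1
        table = descriptive_table(pd.concat([half, dup], ignore_index=True))
        cat = table[(table["test"] == "chi-square") & table["p_value"].notna()]
        degenerate = table["note"].str.contains("skipped")
        assert ((cat["p_value"] > 0.999) | degenerate.loc[cat.index]).all()

    def test_single_level_variable_skips_chi_square(self):
        df = _printed_cohort()
        df["hpsa"] = "partly"
        table = descriptive_table(df)
        hpsa = table[table["variable"] == "hpsa"]
        assert hpsa["note"].str.contains("skipped").all()
        assert hpsa["p_value"].isna().all()

    def test_single_group_rejected(self):
        df = _printed_cohort()
        with pytest.raises(ValueError):
            descriptive_table(df[df["outcome"] == 0])
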