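import datetime as dt

import pandas as pd
import pytest

from trialemu.cohort import CriterionConfig, Registry, cohorts_frame, run_attrition
from trialemu.synthetic import SimConfig, default_trial_roster, generate_registry, trial_frame

ALL_CRITERIA_8PCT = 0.08


@pytest.fixture(scope="session")
def clean_bundle():
    """Registry with zero seeded violations (every eye eligible)."""
    cfg = SimConfig(n_patients=250, seed=11)
    registry, truth = generate_registry(cfg)
    return cfg, registry, truth


@pytest.fixture(scope="session")
def violated_bundle():
    """Registry where every criterion is seeded to fail on ~8% of eyes."""
    from trialemu.cohort import CHECKABLE_CRITERIA

    cfg = SimConfig(
        n_patients=400,
        seed=7,
        violation_fractions={c: ALL_CRITERIA_8PCT for c in CHECKABLE_CRITERIA},
    )
    registry, truth = generate_registry(cfg)
    return cfg, registry, truth


@pytest.fixture(scope="session")
def clean_cohorts(clean_bundle):
    _, registry, _ = clean_bundle
    cohorts, table = run_attrition(registry, CriterionConfig())
    return cohorts, table, cohorts_frame(cohorts)


@pytest.fixture(scope="session")
def trial_df():
    return trial_frame(default_trial_roster(seed=5))


def make_registry(
    patients=None,
    encounters=None,
    injections=None,
    diagnoses=None,
    procedures=None,
    va=None,
    iop=None,
) -> Registry:
    """Hand-built mini registry; omitted tables come up empty."""

    def frame(rows, cols):
        return pd.DataFrame(rows or [], columns=cols)

    reg = Registry(
        patients=frame(patients, ["patient_id", "age_at_first_record", "gender", "race"]),
        encounters=frame(encounters, ["patient_id", "date", "provider_type"]),
        injections=frame(injections, ["patient_id", "laterality", "date", "drug"]),
        diagnoses=frame(diagnoses, ["patient_id", "laterality", "date", "code_category"]),
        procedures=frame(procedures, ["patient_id", "laterality", "date", "category"]),
        va=frame(va, ["patient_id", "laterality", "date", "snellen_num", "snellen_den"]),
        iop=frame(iop, ["patient_id", "laterality", "date", "mmhg"]),
    )
    reg.diagnoses["laterality"] = reg.diagnoses["laterality"].astype(object)
    return reg


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)
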