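import pandas as pd
import pytest

from matgrade.schema import FIELDS, coerce_cohort
from matgrade.simulate import SimConfig, generate_cohort, truth_table

_CATEGORY_DEFAULTS = {
    "ethnicity": "white",
    "literacy": "secondary_or_university",
    "marital_status": "married_or_stable",
    "parity": "multipara",
    "labour_onset": "spontaneous",
    "delivery_mode": "vaginal",
    "death_status": "alive",
    "vital_status_at_birth": "live",
    "child_discharge_status": "alive",
}
_NUMERIC_DEFAULTS = {
    "maternal_age": 25,
    "prenatal_visits": 6,
    "hospital_stay_days": 2,
    "gestational_age_weeks": 39.0,
    "birthweight_g": 3200.0,
    "apgar5": 9,
}


def blank_record(record_id="r0", cluster_id="C00", **overrides) -> dict:
    """A schema-complete record with no morbidity; override fields as needed."""
    rec = {}
    for name, spec in FIELDS.items():
        if spec.kind == "flag":
            rec[name] = False
        elif name in _CATEGORY_DEFAULTS:
            rec[name] = _CATEGORY_DEFAULTS[name]
        else:
            rec[name] = _NUMERIC_DEFAULTS.get(name)
    rec["record_id"] = record_id
    rec["cluster_id"] = cluster_id
    rec.update(overrides)
    return rec


def cohort_from_records(records) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        if "record_id" not in rec or rec["record_id"] == "r0":
            rec = {**rec, "record_id": f"r{i}"}
        rows.append(rec)
    return coerce_cohort(pd.DataFrame(rows, columns=list(FIELDS)))


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11, n_records=8000)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def default_truth(default_config, default_cohort):
    return truth_table(default_config, default_cohort)
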