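"""Severity grading: rules, precedence, partition, and an independent
brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from matgrade.classifier import (
    SeverityClassifier,
    classify_cohort,
    is_md,
    meets_criteria,
    neonatal_near_miss,
)
from matgrade.criteria import CriteriaConfigError, CriterionRule, criteria_from_dict, default_criteria
from matgrade.schema import LSMM_FLAGS, MNM_FLAGS, PLTC_FLAGS, SEVERITY_LEVELS

from conftest import blank_record, cohort_from_records

# ---------------------------------------------------------------------------
# Independent oracle: a record-at-a-time evaluator of the default rule lists,
# restated as plain data, sharing no code with the vectorised classifier.
# ---------------------------------------------------------------------------
ORACLE_MNM_SINGLE = ("eclampsia_or_mgso4", "cardiac_disease", "renal_disease")
ORACLE_PLTC = PLTC_FLAGS + ("blood_transfusion",)
ORACLE_LSMM = LSMM_FLAGS


def oracle_classify(rec: dict) -> str:
    if rec.get("death_status") in ("died_at_facility", "died_in_transport_or_referral"):
        return "MD"
    def on(f):
        return rec.get(f) is True
    stay = rec.get("hospital_stay_days")
    if (
        any(on(f) for f in ORACLE_MNM_SINGLE)
        or (stay is not None and not pd.isna(stay) and stay > 7)
        or (on("blood_transfusion") and on("haemorrhage_any"))
    ):
        return "MNM"
    if any(on(f) for f in ORACLE_PLTC):
        return "PLTC"
    if any(on(f) for f in ORACLE_LSMM):
        return "LSMM"
    return "NONE"


@pytest.fixture(scope="module")
def clf():
    return SeverityClassifier().fit()


@pytest.mark.parametrize(
    "status,expected",
    [("died_at_facility", True), ("alive", False), ("died_in_transport_or_referral", True), (None, False)],
)
def test_is_md(status, expected):
    cohort = cohort_from_records([blank_record(death_status=status)])
    assert is_md(cohort)[0] is np.bool_(expected)


@pytest.mark.parametrize(
    "overrides,expected",
    [
        ({"eclampsia_or_mgso4": True}, "MNM"),
        ({"cardiac_disease": True}, "MNM"),
        ({"hospital_stay_days": 8}, "MNM"),
        ({"hospital_stay_days": 7}, "NONE"),
        ({"blood_transfusion": True, "haemorrhage_any": True}, "MNM"),
        # transfusion without haemorrhage: not a near miss, but a PLTC ("any blood transfusion")
        ({"blood_transfusion": True}, "PLTC"),
        ({"haemorrhage_any": True}, "NONE"),
        ({"severe_hypertension": True}, "PLTC"),
        ({"anaemia": True}, "LSMM"),
        ({}, "NONE"),
        # missing flag states never satisfy a criterion
        ({"eclampsia_or_mgso4": None, "anaemia": None}, "NONE"),
    ],
)
def test_default_rule_table(clf, overrides, expected):
    cohort = cohort_from_records([blank_record(**overrides)])
    assert clf.predict(cohort)[0] == expected
    assert oracle_classify(blank_record(**overrides)) == expected


def test_combined_rule_semantics(clf):
    crit = clf.criteria_
    only_transfusion = cohort_from_records([blank_record(blood_transfusion=True)])
    both = cohort_from_records([blank_record(blood_transfusion=True, haemorrhage_any=True)])
    assert not meets_criteria(only_transfusion, crit["MNM"])[0]
    assert meets_criteria(only_transfusion, crit["PLTC"])[0]
    assert meets_criteria(both, crit["MNM"])[0]


def test_precedence_death_beats_everything(clf):
    rec = blank_record(death_status="died_at_facility", hospital_stay_days=30)
    rec.update({f: True for f in MNM_FLAGS + PLTC_FLAGS + LSMM_FLAGS})
    assert clf.predict(cohort_from_records([rec]))[0] == "MD"


def test_precedence_mnm_beats_lsmm(clf):
    rec = blank_record(eclampsia_or_mgso4=True, anaemia=True)
    assert clf.predict(cohort_from_records([rec]))[0] == "MNM"


def test_partition_property(default_cohort, clf):
    labels = clf.predict(default_cohort)
    counts = pd.Series(labels).value_counts()
    assert set(counts.index) <= set(SEVERITY_LEVELS)
    assert counts.sum() == len(default_cohort)


_flag_lists = st.lists(st.sampled_from(MNM_FLAGS + PLTC_FLAGS + LSMM_FLAGS), max_size=6, unique=True)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    flags=_flag_lists,
    stay=st.integers(min_value=0, max_value=15),
    died=st.booleans(),
    escalation=st.sampled_from(["died", "eclampsia_or_mgso4", "uterine_rupture"]),
)
def test_monotone_precedence(flags, stay, died, escalation):
    """Adding a higher-severity condition never lowers the class."""
    clf = SeverityClassifier().fit()
    rank = {lvl: i for i, lvl in enumerate(SEVERITY_LEVELS)}  # 0 = worst
    base = blank_record(hospital_stay_days=stay)
    base.update({f: True for f in flags})
    if died:
        base["death_status"] = "died_at_facility"
    before = clf.predict(cohort_from_records([base]))[0]
    worse = dict(base)
    if escalation == "died":
        worse["death_status"] = "died_at_facility"
    else:
        worse[escalation] = True
    after = clf.predict(cohort_from_records([worse]))[0]
    assert rank[after] <= rank[before]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=2**20))
def test_classifier_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    recs = []
    all_flags = MNM_FLAGS + PLTC_FLAGS + LSMM_FLAGS
    for i in range(25):
        rec = blank_record(record_id=f"r{i}")
        for f in all_flags:
            rec[f] = [True, False, None][rng.integers(0, 3)]
        rec["hospital_stay_days"] = int(rng.integers(0, 12))
        rec["death_status"] = ["alive", "alive", "alive", "died_at_facility"][rng.integers(0, 4)]
        recs.append(rec)
    cohort = cohort_from_records(recs)
    got = SeverityClassifier().fit().predict(cohort)
    want = [oracle_classify(r) for r in recs]
    assert list(got) == want


def test_label_fidelity_on_generated_truth(default_cohort, default_truth):
    classified = classify_cohort(default_cohort)
    assert (classified["severity"].to_numpy() == default_truth["true_class"].to_numpy()).all()


# -- criteria configuration --------------------------------------------------

def test_rule_referencing_unknown_field_is_config_error():
    with pytest.raises(CriteriaConfigError, match="not_a_field"):
        CriterionRule(field="not_a_field", comparator="is_present").validate()


def test_config_requires_all_levels():
    with pytest.raises(CriteriaConfigError):
        criteria_from_dict({"MNM": {"rules": [{"field": "anaemia", "comparator": "is_present"}]}})


def test_single_criterion_transfusion_reading_is_selectable():
    """Moving blood transfusion into the MNM single-rule list flips the reading."""
    import yaml
    from importlib import resources

    cfg = yaml.safe_load(
        resources.files("matgrade.data").joinpath("default_criteria.yaml").read_text(encoding="utf-8")
    )
    cfg["MNM"]["rules"].append({"field": "blood_transfusion", "comparator": "is_present"})
    crit = criteria_from_dict(cfg)
    cohort = cohort_from_records([blank_record(blood_transfusion=True)])
    assert SeverityClassifier(criteria=crit).fit().predict(cohort)[0] == "MNM"


# -- neonatal near miss ------------------------------------------------------

@pytest.mark.parametrize(
    "overrides,expected",
    [
        ({"birthweight_g": 1749, "apgar5": 9, "gestational_age_weeks": 39}, True),
        ({"birthweight_g": 1750, "apgar5": 7, "gestational_age_weeks": 33}, False),
        ({"birthweight_g": None, "apgar5": 6, "gestational_age_weeks": None}, True),
        ({"gestational_age_weeks": 32.9, "birthweight_g": 3000, "apgar5": 9}, True),
    ],
)
def test_neonatal_near_miss_thresholds(overrides, expected):
    cohort = cohort_from_records([blank_record(**overrides)])
    assert neonatal_near_miss(cohort)[0] == expected


def test_neonatal_near_miss_not_applicable_cases():
    cohort = cohort_from_records(
        [
            blank_record(vital_status_at_birth="fetal_death", birthweight_g=900),
            blank_record(birthweight_g=None, apgar5=None, gestational_age_weeks=None),
        ]
    )
    out = neonatal_near_miss(cohort)
    assert out.isna().all()
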