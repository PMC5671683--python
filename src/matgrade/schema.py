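"""Registry record schema, tri-state flag semantics and cohort CSV I/O.

A cohort is a :class:`pandas.DataFrame` with one row per woman/delivery and
the columns listed in :data:`FIELDS`.  Condition flags are *tri-state*:
present, absent, or missing.  In memory they use the pandas nullable
``boolean`` dtype (``True`` / ``False`` / ``pd.NA``); on disk they are
``1`` / ``0`` / empty cell.  Missing is a first-class state — registries can
only act on recorded diagnoses, so downstream classification treats missing
as criterion-not-met rather than imputing.

CSV dialect: UTF-8, comma-separated, header row naming every field, empty
cell = missing.  ``read_cohort(write_cohort(c))`` reproduces ``c``
field-for-field, including missing states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

#: Severity gradient labels, from worst to best.
SEVERITY_LEVELS = ("MD", "MNM", "PLTC", "LSMM", "NONE")


class SchemaError(ValueError):
    """A file does not conform to the cohort schema (e.g. unknown column)."""


class CohortValidationError(ValueError):
    """A record violates a schema invariant (raised in strict mode)."""


@dataclass(frozen=True)
class FieldSpec:
    """One column of the cohort data dictionary."""

    name: str
    kind: str  # "id" | "category" | "int" | "float" | "flag"
    categories: tuple[str, ...] = ()
    lo: float | None = None  # inclusive lower bound, when bounded
    hi: float | None = None  # inclusive upper bound
    doc: str = ""


# Severity-criterion condition flags.  Names follow the registry's diagnosis
# proxies; `prev_*` fields are pre-existing (history) conditions, distinct
# from same-named index-pregnancy event flags.
MNM_FLAGS = (
    "blood_transfusion",
    "haemorrhage_any",
    "eclampsia_or_mgso4",
    "cardiac_disease",
    "renal_disease",
)
PLTC_FLAGS = (
    "abruptio_placentae",
    "ectopic_pregnancy",
    "uterine_rupture",
    "postpartum_haemorrhage",
    "puerperal_sepsis",
    "puerperal_infection",
    "severe_preeclampsia_no_mgso4",
    "severe_hypertension",
    "placenta_previa_with_haemorrhage",
    "other_severe_condition",
)
LSMM_FLAGS = (
    "anaemia",
    "hiv_positive",
    "diabetes",
    "antenatal_admission",
    "ovular_infection",
    "urinary_tract_infection",
    "other_maternal_condition",
    "retained_placenta",
    "referred",
)
PREVIOUS_FLAGS = (
    "prev_diabetes",
    "prev_hypertension",
    "prev_preeclampsia",
    "prev_eclampsia",
    "prev_cardiac_disease",
    "prev_renal_disease",
    "prev_other_severe",
    "prev_any",
)


def _flag(name: str, doc: str = "") -> FieldSpec:
    return FieldSpec(name, "flag", doc=doc)


FIELDS: dict[str, FieldSpec] = {
    f.name: f
    for f in [
        FieldSpec("record_id", "id", doc="opaque unique identifier"),
        FieldSpec("cluster_id", "id", doc="country/site identifier (primary sampling unit)"),
        FieldSpec("maternal_age", "int", lo=10, hi=55, doc="maternal age in completed years"),
        FieldSpec("ethnicity", "category", ("white", "mixed", "other")),
        FieldSpec("literacy", "category", ("none_or_primary", "secondary_or_university")),
        FieldSpec("marital_status", "category", ("married_or_stable", "single_or_other")),
        FieldSpec("parity", "category", ("nullipara", "multipara")),
        FieldSpec("prenatal_visits", "int", lo=0, doc="number of prenatal care visits"),
        _flag("risk_exposure", "smoking, drugs, alcohol or violence (composite as recorded)"),
        _flag("previous_csection"),
        FieldSpec("labour_onset", "category", ("spontaneous", "induced", "elective_csection")),
        FieldSpec("delivery_mode", "category", ("csection", "vaginal")),
        FieldSpec(
            "death_status",
            "category",
            ("alive", "died_at_facility", "died_in_transport_or_referral"),
        ),
        FieldSpec("hospital_stay_days", "int", lo=0, doc="total facility stay for the childbirth admission"),
        *[_flag(n) for n in MNM_FLAGS],
        *[_flag(n) for n in PLTC_FLAGS],
        *[_flag(n) for n in LSMM_FLAGS],
        *[_flag(n) for n in PREVIOUS_FLAGS],
        FieldSpec("gestational_age_weeks", "float", lo=10, hi=46),
        FieldSpec("birthweight_g", "float", lo=200, hi=7000),
        FieldSpec("apgar5", "int", lo=0, hi=10, doc="Apgar score at the 5th minute"),
        FieldSpec("vital_status_at_birth", "category", ("live", "fetal_death")),
        FieldSpec("child_discharge_status", "category", ("alive", "neonatal_death", "referred")),
    ]
}

ALL_FLAGS = MNM_FLAGS + PLTC_FLAGS + LSMM_FLAGS + PREVIOUS_FLAGS

_DTYPES = {"id": "object", "category": "object", "int": "Int64", "float": "Float64", "flag": "boolean"}


def empty_cohort() -> pd.DataFrame:
    """Return a zero-row cohort frame with the full schema and dtypes."""
    df = pd.DataFrame({name: pd.Series(dtype=_DTYPES[f.kind]) for name, f in FIELDS.items()})
    df.attrs["schema_version"] = SCHEMA_VERSION
    return df


def data_dictionary() -> pd.DataFrame:
    """Machine-readable data dictionary (one row per schema field)."""
    return pd.DataFrame(
        [
            {
                "field": f.name,
                "kind": f.kind,
                "categories": "|".join(f.categories),
                "lo": f.lo,
                "hi": f.hi,
                "doc": f.doc,
            }
            for f in FIELDS.values()
        ]
    )


@dataclass
class ValidationReport:
    """Outcome of cohort validation.

    ``invalid`` maps record_id -> list of violated invariants;
    ``missing_fraction`` is the per-field fraction of missing cells.
    """

    n_records: int
    invalid: dict = field(default_factory=dict)
    missing_fraction: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.invalid


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for name, spec in FIELDS.items():
        col = df[name]
        if spec.kind == "flag":
            s = col.map({"1": True, "0": False, True: True, False: False, 1: True, 0: False})
            out[name] = pd.array(s, dtype="boolean")
        elif spec.kind == "int":
            out[name] = pd.array(pd.to_numeric(col, errors="raise"), dtype="Int64")
        elif spec.kind == "float":
            out[name] = pd.array(pd.to_numeric(col, errors="raise"), dtype="Float64")
        else:
            out[name] = col.astype("object").where(col.notna(), None)
            out[name] = out[name].where(pd.notna(out[name]), other=pd.NA)
    return out


def validate_cohort(df: pd.DataFrame) -> ValidationReport:
    """Check schema invariants; never raises.

    Checked invariants: unique ``record_id``; category values drawn from the
    declared vocabulary; numeric bounds (maternal age 10–55, Apgar 0–10,
    gestational age 10–46 weeks, birthweight 200–7000 g, non-negative counts);
    ``prev_any`` present iff at least one listed previous condition is present
    (only testable when the components are non-missing).
    """
    report = ValidationReport(n_records=len(df))
    report.missing_fraction = {name: float(df[name].isna().mean()) if len(df) else 0.0 for name in FIELDS}

    def flag_rows(mask: pd.Series, message: str) -> None:
        for rid in df.loc[mask.fillna(False), "record_id"]:
            report.invalid.setdefault(rid, []).append(message)

    dup = df["record_id"].duplicated(keep=False)
    flag_rows(dup, "duplicate record_id")

    for name, spec in FIELDS.items():
        col = df[name]
        if spec.kind == "category":
            bad = col.notna() & ~col.isin(spec.categories)
            flag_rows(bad, f"{name}: value outside {spec.categories}")
        elif spec.kind in ("int", "float"):
            if spec.lo is not None:
                flag_rows(col < spec.lo, f"{name} < {spec.lo}")
            if spec.hi is not None:
                flag_rows(col > spec.hi, f"{name} > {spec.hi}")

    # prev_any consistency: decidable only where all components are recorded
    components = [c for c in PREVIOUS_FLAGS if c != "prev_any"]
    comp = df[list(components)]
    any_comp = comp.fillna(False).any(axis=1)
    decidable = df["prev_any"].notna() & comp.notna().all(axis=1)
    mismatch = decidable & (df["prev_any"].fillna(False) != any_comp)
    flag_rows(mismatch, "prev_any inconsistent with listed previous conditions")
    return report


def read_cohort(path, strict: bool = False) -> pd.DataFrame:
    """Read a cohort CSV into a schema-typed DataFrame.

    Empty cells become the missing state (``pd.NA``).  Unknown or absent
    columns raise :class:`SchemaError`.  Invariant violations raise
    :class:`CohortValidationError` when ``strict`` is true; otherwise they
    are logged and recorded in ``df.attrs["invalid_records"]``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""], encoding="utf-8")
    unknown = set(raw.columns) - set(FIELDS)
    if unknown:
        raise SchemaError(f"unknown column(s): {sorted(unknown)}")
    absent = set(FIELDS) - set(raw.columns)
    if absent:
        raise SchemaError(f"missing column(s): {sorted(absent)}")
    df = _coerce(raw)
    report = validate_cohort(df)
    if report.invalid:
        if strict:
            raise CohortValidationError(
                f"{len(report.invalid)} invalid record(s): "
                + "; ".join(f"{rid}: {', '.join(msgs)}" for rid, msgs in list(report.invalid.items())[:10])
            )
        for rid, msgs in report.invalid.items():
            logger.warning("record %s: %s", rid, "; ".join(msgs))
    df.attrs["schema_version"] = SCHEMA_VERSION
    df.attrs["invalid_records"] = report.invalid
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (UTF-8, empty cell = missing); round-trip safe."""
    out = pd.DataFrame(index=cohort.index)
    for name, spec in FIELDS.items():
        col = cohort[name]
        if spec.kind == "flag":
            out[name] = col.map({True: "1", False: "0"})
        elif spec.kind == "int":
            out[name] = col.astype("object").map(lambda v: "" if pd.isna(v) else str(int(v)))
        elif spec.kind == "float":
            out[name] = col.astype("object").map(lambda v: "" if pd.isna(v) else repr(float(v)))
        else:
            out[name] = col
    out.to_csv(path, index=False, encoding="utf-8", na_rep="")


def coerce_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce an arbitrary same-shaped frame to schema dtypes (for builders)."""
    missing = set(FIELDS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")
    out = _coerce(df)
    out.attrs["schema_version"] = SCHEMA_VERSION
    return out
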