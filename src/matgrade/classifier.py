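"""Severity grading: one mutually exclusive class per record, plus the
neonatal near-miss composite.

Records are graded down a fixed precedence ladder — maternal death (MD),
maternal near miss (MNM), potentially life-threatening condition (PLTC),
less severe maternal morbidity (LSMM), then no morbidity (NONE) — so the
five classes partition any cohort and adding a higher-severity condition can
never lower a record's class.  MD is determined by the death-status field
alone; the other levels by configurable :class:`~matgrade.criteria.CriteriaSet`
rules.  Missing flag states never satisfy a criterion.

Derived unions used by the indicator panel: SMO = MD ∪ MNM (severe maternal
outcome) and AMM = MD ∪ MNM ∪ PLTC ∪ LSMM (any maternal morbidity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .criteria import CONFIGURABLE_LEVELS, CriteriaSet, default_criteria
from .schema import SEVERITY_LEVELS

DIED_STATES = ("died_at_facility", "died_in_transport_or_referral")

#: Neonatal near-miss component thresholds (strict inequalities).
NNM_BIRTHWEIGHT_G = 1750.0
NNM_APGAR5 = 7
NNM_GESTATIONAL_WEEKS = 33.0


def is_md(cohort: pd.DataFrame) -> np.ndarray:
    """True where the woman died at the facility or in transport/referral.

    A missing death status cannot assert a death and maps to False.
    """
    return cohort["death_status"].isin(DIED_STATES).to_numpy(dtype=bool)


def meets_criteria(cohort: pd.DataFrame, criteria: CriteriaSet) -> np.ndarray:
    """Records satisfying any single rule or any combined-rule group."""
    criteria.validate()
    return criteria.evaluate(cohort)


class SeverityClassifier(BaseEstimator):
    """Rule-based grader assigning each record one severity class.

    Parameters
    ----------
    criteria : dict[str, CriteriaSet] or None
        Criteria sets for MNM, PLTC and LSMM.  ``None`` selects the shipped
        registry-proxy defaults.

    Attributes
    ----------
    criteria_ : dict[str, CriteriaSet]
        Validated criteria in use after :meth:`fit`.
    classes_ : ndarray
        The five severity labels in precedence order.
    """

    def __init__(self, criteria: dict[str, CriteriaSet] | None = None):
        self.criteria = criteria

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "SeverityClassifier":
        """Validate the criteria configuration (no parameters are learned)."""
        criteria = self.criteria if self.criteria is not None else default_criteria()
        missing = set(CONFIGURABLE_LEVELS) - set(criteria)
        if missing:
            raise ValueError(f"criteria must define levels {sorted(missing)}")
        for level in CONFIGURABLE_LEVELS:
            criteria[level].validate()
        self.criteria_ = criteria
        self.classes_ = np.asarray(SEVERITY_LEVELS)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Severity label per record, first match in MD > MNM > PLTC > LSMM order."""
        if not hasattr(self, "criteria_"):
            raise ValueError("SeverityClassifier is not fitted; call fit() first")
        labels = np.full(len(X), "NONE", dtype=object)
        unassigned = np.ones(len(X), dtype=bool)
        for level, mask in [
            ("MD", is_md(X)),
            *[(lvl, self.criteria_[lvl].evaluate(X)) for lvl in CONFIGURABLE_LEVELS],
        ]:
            take = unassigned & mask
            labels[take] = level
            unassigned &= ~take
        return labels.astype(str)


def classify_cohort(
    cohort: pd.DataFrame,
    criteria: dict[str, CriteriaSet] | None = None,
    severity_col: str = "severity",
    nnm_col: str = "neonatal_near_miss",
) -> pd.DataFrame:
    """Return a copy of the cohort with severity and neonatal near-miss columns."""
    clf = SeverityClassifier(criteria=criteria).fit()
    out = cohort.copy()
    out[severity_col] = clf.predict(cohort)
    out[nnm_col] = neonatal_near_miss(cohort)
    out.attrs = dict(cohort.attrs)
    return out


def neonatal_near_miss(cohort: pd.DataFrame) -> pd.Series:
    """Neonatal near-miss composite: birthweight < 1750 g, or 5-minute Apgar
    < 7, or gestational age < 33 weeks.

    Missing components are non-qualifying.  The composite is not applicable
    (``pd.NA``) for fetal deaths and when all three components are missing;
    tables count those records as missing.
    """
    bw = cohort["birthweight_g"]
    ap = cohort["apgar5"]
    ga = cohort["gestational_age_weeks"]
    qualifies = (
        (bw < NNM_BIRTHWEIGHT_G).fillna(False)
        | (ap < NNM_APGAR5).fillna(False)
        | (ga < NNM_GESTATIONAL_WEEKS).fillna(False)
    )
    not_applicable = (cohort["vital_status_at_birth"] == "fetal_death") | (
        bw.isna() & ap.isna() & ga.isna()
    )
    out = pd.Series(qualifies, index=cohort.index, dtype="boolean")
    out[not_applicable.fillna(False).astype(bool)] = pd.NA
    return out.rename("neonatal_near_miss")
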