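"""Configurable criteria sets for the severity gradient.

Each severity level below maternal death is defined by a :class:`CriteriaSet`:
a list of single rules (any one suffices) plus optional combined-rule groups
(all members of a group must hold jointly).  Rules reference schema fields by
name and ship as an editable YAML config so additional criteria — e.g. the
full WHO clinical/laboratory/management near-miss set — can be added where a
registry records them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .schema import FIELDS

COMPARATORS = ("is_present", "greater_than", "equals")

#: Levels that carry a configurable criteria set, in precedence order.
CONFIGURABLE_LEVELS = ("MNM", "PLTC", "LSMM")


class CriteriaConfigError(ValueError):
    """A rule references an unknown field or uses an invalid comparator."""


@dataclass(frozen=True)
class CriterionRule:
    field: str
    comparator: str
    value: object = None

    def validate(self) -> None:
        if self.field not in FIELDS:
            raise CriteriaConfigError(f"rule references unknown field {self.field!r}")
        if self.comparator not in COMPARATORS:
            raise CriteriaConfigError(f"unknown comparator {self.comparator!r}")
        kind = FIELDS[self.field].kind
        if self.comparator == "is_present" and kind != "flag":
            raise CriteriaConfigError(f"is_present requires a flag field, got {self.field!r} ({kind})")
        if self.comparator == "greater_than":
            if kind not in ("int", "float"):
                raise CriteriaConfigError(f"greater_than requires a numeric field, got {self.field!r} ({kind})")
            if self.value is None:
                raise CriteriaConfigError("greater_than requires a threshold value")
        if self.comparator == "equals" and self.value is None:
            raise CriteriaConfigError("equals requires a comparison value")

    def evaluate(self, cohort: pd.DataFrame) -> np.ndarray:
        """Vectorised rule evaluation; missing values never satisfy a rule."""
        col = cohort[self.field]
        if self.comparator == "is_present":
            hit = col == True  # noqa: E712 — nullable boolean comparison
        elif self.comparator == "greater_than":
            hit = col > self.value
        else:
            hit = col == self.value
        return hit.fillna(False).to_numpy(dtype=bool)


@dataclass
class CriteriaSet:
    """Criteria for one severity level: OR over `rules` and over AND-groups."""

    level: str
    rules: list[CriterionRule] = field(default_factory=list)
    combined: list[list[CriterionRule]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.rules and not self.combined:
            raise CriteriaConfigError(f"criteria set for {self.level} is empty")
        for r in self.rules:
            r.validate()
        for group in self.combined:
            if not group:
                raise CriteriaConfigError(f"empty combined-rule group in {self.level}")
            for r in group:
                r.validate()

    def evaluate(self, cohort: pd.DataFrame) -> np.ndarray:
        """Boolean mask of records meeting this level's criteria."""
        n = len(cohort)
        hit = np.zeros(n, dtype=bool)
        for r in self.rules:
            hit |= r.evaluate(cohort)
        for group in self.combined:
            joint = np.ones(n, dtype=bool)
            for r in group:
                joint &= r.evaluate(cohort)
            hit |= joint
        return hit


def _parse_rule(d: dict) -> CriterionRule:
    try:
        return CriterionRule(field=d["field"], comparator=d["comparator"], value=d.get("value"))
    except (KeyError, TypeError) as exc:
        raise CriteriaConfigError(f"malformed rule {d!r}") from exc


def criteria_from_dict(cfg: dict) -> dict[str, CriteriaSet]:
    """Build and validate criteria sets from a parsed config mapping."""
    unknown = set(cfg) - set(CONFIGURABLE_LEVELS)
    if unknown:
        raise CriteriaConfigError(f"unknown severity level(s) in config: {sorted(unknown)}")
    out: dict[str, CriteriaSet] = {}
    for level in CONFIGURABLE_LEVELS:
        if level not in cfg:
            raise CriteriaConfigError(f"config must define criteria for {level}")
        block = cfg[level] or {}
        cs = CriteriaSet(
            level=level,
            rules=[_parse_rule(d) for d in block.get("rules", [])],
            combined=[[_parse_rule(d) for d in grp] for grp in block.get("combined", [])],
        )
        cs.validate()
        out[level] = cs
    return out


def load_criteria(path) -> dict[str, CriteriaSet]:
    """Load a criteria config from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return criteria_from_dict(yaml.safe_load(fh))


def default_criteria() -> dict[str, CriteriaSet]:
    """The registry-proxy criteria shipped with the package."""
    text = resources.files("matgrade.data").joinpath("default_criteria.yaml").read_text(encoding="utf-8")
    return criteria_from_dict(yaml.safe_load(text))
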