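"""Surveillance indicator panel for a classified cohort.

Percentages are over all women; ratio-type indicators are per live births:
the maternal mortality ratio (MMR) per 100,000 live births, and the near
miss (MNMR), severe maternal outcome (SMOR), potentially life-threatening
condition (PLTCR), less severe morbidity (LSMMR) and any-morbidity (AMMR)
ratios per 1,000 live births.  The morbidity-to-death ratio counts survivors
with any degree of morbidity per maternal death: (AMM − MD) / MD.

Unrounded values are always retained; ``IndicatorPanel.rounded()`` applies
the display convention (ratios to 1 decimal, percentages to 2 decimals below
1% and 1 decimal otherwise, morbidity-to-death ratio to the nearest integer).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .schema import SEVERITY_LEVELS

logger = logging.getLogger(__name__)

MORBIDITY_LEVELS = ("MD", "MNM", "PLTC", "LSMM")


def count_live_births(cohort: pd.DataFrame) -> int:
    """Number of records with a live birth (missing vital status counts as
    non-live and is logged)."""
    n_missing = int(cohort["vital_status_at_birth"].isna().sum())
    if n_missing:
        logger.info("vital_status_at_birth missing for %d records; counted as non-live", n_missing)
    return int((cohort["vital_status_at_birth"] == "live").sum())


@dataclass
class IndicatorPanel:
    """Counts, percentages over women, and per-live-birth ratios."""

    n_women: int
    n_live_births: int
    counts: dict = field(default_factory=dict)  # MD, MNM, SMO, PLTC, LSMM, AMM, NONE
    percentages: dict = field(default_factory=dict)  # % of women, unrounded
    mmr: float = math.nan  # per 100,000 live births
    mnmr: float = math.nan  # per 1,000 live births
    smor: float = math.nan
    pltcr: float = math.nan
    lsmmr: float = math.nan
    ammr: float = math.nan
    morbidity_to_death_ratio: float = math.nan  # NaN when MD = 0 (not defined)

    def rounded(self) -> dict:
        """Display-rounded panel: ratios 1 d.p., percentages 1–2 d.p.,
        morbidity-to-death ratio to the nearest integer."""
        pct = {
            k: round(v, 2 if v < 1 else 1) for k, v in self.percentages.items()
        }
        out = {
            "n_women": self.n_women,
            "n_live_births": self.n_live_births,
            "counts": dict(self.counts),
            "percentages": pct,
            "MMR": round(self.mmr, 1),
            "MNMR": round(self.mnmr, 1),
            "SMOR": round(self.smor, 1),
            "PLTCR": round(self.pltcr, 1),
            "LSMMR": round(self.lsmmr, 1),
            "AMMR": round(self.ammr, 1),
        }
        out["morbidity_to_death_ratio"] = (
            None if math.isnan(self.morbidity_to_death_ratio) else round(self.morbidity_to_death_ratio)
        )
        return out


def indicator_panel_from_counts(
    md: int, mnm: int, pltc: int, lsmm: int, none: int, n_live_births: int
) -> IndicatorPanel:
    """Build the panel from mutually exclusive class counts.

    Raises ``ValueError`` on zero live births.  With zero maternal deaths the
    morbidity-to-death ratio is not defined and reported as NaN.
    """
    if n_live_births <= 0:
        raise ValueError("indicator panel requires n_live_births > 0")
    n_women = md + mnm + pltc + lsmm + none
    smo = md + mnm
    amm = md + mnm + pltc + lsmm
    if n_live_births > n_women:
        logger.warning(
            "live births (%d) exceed women (%d); plausible only with multiple gestation",
            n_live_births,
            n_women,
        )
    counts = {"MD": md, "MNM": mnm, "SMO": smo, "PLTC": pltc, "LSMM": lsmm, "AMM": amm, "NONE": none}
    pct = {k: 100.0 * counts[k] / n_women for k in counts}
    per_1000 = lambda c: 1000.0 * c / n_live_births  # noqa: E731
    return IndicatorPanel(
        n_women=n_women,
        n_live_births=n_live_births,
        counts=counts,
        percentages=pct,
        mmr=100000.0 * md / n_live_births,
        mnmr=per_1000(mnm),
        smor=per_1000(smo),
        pltcr=per_1000(pltc),
        lsmmr=per_1000(lsmm),
        ammr=per_1000(amm),
        morbidity_to_death_ratio=(amm - md) / md if md > 0 else math.nan,
    )


def indicator_panel(classified: pd.DataFrame, severity_col: str = "severity") -> IndicatorPanel:
    """Compute the panel from a classified cohort (severity column present)."""
    if severity_col not in classified.columns:
        raise ValueError(f"cohort has no {severity_col!r} column; classify it first")
    vc = classified[severity_col].value_counts()
    counts = {lvl: int(vc.get(lvl, 0)) for lvl in SEVERITY_LEVELS}
    return indicator_panel_from_counts(
        md=counts["MD"],
        mnm=counts["MNM"],
        pltc=counts["PLTC"],
        lsmm=counts["LSMM"],
        none=counts["NONE"],
        n_live_births=count_live_births(classified),
    )
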