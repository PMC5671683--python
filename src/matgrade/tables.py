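"""Stratified outcome tables with cluster-design-corrected chi-square tests.

Registry records arrive clustered by country (the primary sampling unit,
PSU).  Cell proportions estimated from clustered data carry a *design
effect* — the ratio of their actual sampling variance to the variance a
simple random sample of the same size would give.  Ignoring it makes the
Pearson chi-square anticonservative when outcomes correlate within PSUs.

``rao_scott_chi2`` applies the first-order correction: the Pearson statistic
is divided by the mean estimated cell design effect, and the p-value is read
from the chi-square distribution on the unchanged degrees of freedom.  Cell
proportion variances are estimated by the standard with-replacement PSU
linearisation.  With a single cluster the design effect is 1 by construction
and the corrected test coincides with the classical Pearson test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import FIELDS, SEVERITY_LEVELS

logger = logging.getLogger(__name__)


@dataclass
class StratTable:
    """One variable cross-tabulated against the severity classes."""

    variable: str
    categories: list
    counts: pd.DataFrame  # rows = categories, columns = severity classes
    column_percent: pd.DataFrame  # % within each severity class
    missing_fraction: float  # fraction of records excluded for a missing variable
    n_clusters: int = 1
    chi2_uncorrected: float = math.nan
    chi2_corrected: float = math.nan
    p_corrected: float = math.nan
    design_effect: float = math.nan
    df: int = 0
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "categories": [str(c) for c in self.categories],
            "counts": {str(c): self.counts.loc[c].astype(int).to_dict() for c in self.counts.index},
            "column_percent": {
                str(c): {k: float(v) for k, v in self.column_percent.loc[c].items()}
                for c in self.column_percent.index
            },
            "missing_fraction": self.missing_fraction,
            "n_clusters": self.n_clusters,
            "chi2_uncorrected": _none_if_nan(self.chi2_uncorrected),
            "chi2_corrected": _none_if_nan(self.chi2_corrected),
            "p_corrected": _none_if_nan(self.p_corrected),
            "design_effect": _none_if_nan(self.design_effect),
            "df": self.df,
            "note": self.note,
        }


def _none_if_nan(x: float):
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)


def _variable_values(classified: pd.DataFrame, variable: str) -> pd.Series:
    if variable not in classified.columns:
        raise ValueError(f"unknown variable {variable!r}")
    col = classified[variable]
    if variable in FIELDS and FIELDS[variable].kind == "flag":
        col = col.map({True: "present", False: "absent"})
    return col


def crosstab(
    classified: pd.DataFrame,
    variable: str,
    severity_col: str = "severity",
    classes: tuple = SEVERITY_LEVELS,
) -> StratTable:
    """Counts and within-class percentages of ``variable`` by severity class.

    Records with a missing variable are excluded from the cells and reported
    in ``missing_fraction``, mirroring per-variable footnotes.
    """
    sev = classified[severity_col]
    col = _variable_values(classified, variable)
    missing = col.isna()
    sub = pd.DataFrame({"v": col[~missing], "s": sev[~missing]})
    tab = pd.crosstab(sub["v"], sub["s"])
    tab = tab.reindex(columns=[c for c in classes if c in tab.columns], fill_value=0)
    col_tot = tab.sum(axis=0)
    pct = 100.0 * tab / col_tot.replace(0, np.nan)
    return StratTable(
        variable=variable,
        categories=list(tab.index),
        counts=tab,
        column_percent=pct,
        missing_fraction=float(missing.mean()) if len(classified) else 0.0,
    )


def _pearson_chi2(tab: np.ndarray) -> tuple[float, int]:
    chi2, _, dof, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(dof)


def rao_scott_chi2(
    row_values,
    col_values,
    cluster_labels,
) -> dict:
    """First-order design-effect-corrected chi-square for two categorical
    record-level variables.

    Parameters are per-record arrays: the stratifying variable, the severity
    (or any categorical outcome), and the PSU label.  Returns a dict with the
    uncorrected Pearson statistic, the corrected statistic (Pearson divided
    by the mean cell design effect), the corrected p-value on the unchanged
    degrees of freedom, the design effect, the df and the cluster count.

    With fewer than two clusters the design effect cannot be estimated; the
    test falls back to the uncorrected Pearson test with a warning.  A table
    with any zero margin is degenerate: the result carries NaN statistics and
    an explanatory note.
    """
    row = pd.Series(np.asarray(row_values, dtype=object))
    col = pd.Series(np.asarray(col_values, dtype=object))
    clu = pd.Series(np.asarray(cluster_labels, dtype=object))
    keep = row.notna().to_numpy() & col.notna().to_numpy()
    row, col, clu = row[keep], col[keep], clu[keep]
    n = len(row)
    tab = pd.crosstab(row, col)
    out = {
        "chi2_uncorrected": math.nan,
        "chi2_corrected": math.nan,
        "p_corrected": math.nan,
        "design_effect": math.nan,
        "df": 0,
        "n_clusters": int(clu.nunique()),
        "note": "",
    }
    if tab.shape[0] < 2 or tab.shape[1] < 2 or (tab.to_numpy().sum(axis=0) == 0).any() or (
        tab.to_numpy().sum(axis=1) == 0
    ).any():
        out["note"] = "degenerate table: fewer than two non-empty rows/columns"
        return out

    chi2, dof = _pearson_chi2(tab.to_numpy())
    out["chi2_uncorrected"] = chi2
    out["df"] = dof

    n_clusters = int(clu.nunique())
    if n_clusters < 2:
        logger.warning("fewer than 2 clusters: falling back to the uncorrected Pearson test")
        out.update(
            chi2_corrected=chi2,
            p_corrected=float(stats.chi2.sf(chi2, dof)),
            design_effect=1.0,
            note="single cluster: design effect fixed at 1",
        )
        return out

    deff = _mean_cell_design_effect(row, col, clu, tab)
    corrected = chi2 / deff
    out.update(
        chi2_corrected=float(corrected),
        p_corrected=float(stats.chi2.sf(corrected, dof)),
        design_effect=float(deff),
    )
    return out


def _mean_cell_design_effect(row: pd.Series, col: pd.Series, clu: pd.Series, tab: pd.DataFrame) -> float:
    """Mean design effect of the cell proportions.

    For each table cell, the proportion variance under the clustered design
    is estimated by the with-replacement PSU linearisation
    ``G/(G-1) * sum_g (x_g - p*n_g)^2 / n^2`` and divided by the binomial
    variance ``p(1-p)/n``.  Cells with p in {0, 1} carry no information and
    are skipped; if none remain the design effect is 1.
    """
    n = len(row)
    groups = pd.crosstab(index=[row, col], columns=clu)  # (cell) x cluster counts
    n_g = clu.value_counts().reindex(groups.columns).to_numpy(dtype=float)
    G = groups.shape[1]
    deffs = []
    for cell in groups.index:
        x_g = groups.loc[cell].to_numpy(dtype=float)
        p = x_g.sum() / n
        if p <= 0.0 or p >= 1.0:
            continue
        resid = x_g - p * n_g
        var_clu = (G / (G - 1)) * np.sum(resid**2) / n**2
        deffs.append(var_clu / (p * (1.0 - p) / n))
    return float(np.mean(deffs)) if deffs else 1.0


def build_table(
    classified: pd.DataFrame,
    variable: str,
    cluster_col: str = "cluster_id",
    severity_col: str = "severity",
    classes: tuple = SEVERITY_LEVELS,
) -> StratTable:
    """Cross-tabulate ``variable`` by severity and attach the corrected test."""
    table = crosstab(classified, variable, severity_col=severity_col, classes=classes)
    col = _variable_values(classified, variable)
    res = rao_scott_chi2(col, classified[severity_col], classified[cluster_col])
    table.n_clusters = res["n_clusters"]
    table.chi2_uncorrected = res["chi2_uncorrected"]
    table.chi2_corrected = res["chi2_corrected"]
    table.p_corrected = res["p_corrected"]
    table.design_effect = res["design_effect"]
    table.df = res["df"]
    table.note = res["note"]
    return table
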