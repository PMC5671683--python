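"""Crude and adjusted prevalence ratios versus the no-morbidity group.

The analysis population for an outcome class is that class plus the
no-morbidity reference group.  The crude prevalence ratio for an exposure is
the ratio of outcome prevalence among the exposed to that among the
unexposed, PR = [a/(a+b)] / [c/(c+d)], with the 95% CI from the Katz log
method or, with PSU labels, from a cluster-robust sandwich variance.

Adjusted PRs come from a log-link binomial model of the outcome on all
covariates simultaneously; because the log-binomial likelihood often fails
to converge near the boundary, the fit falls back to the modified-Poisson
estimator (log-link Poisson with a robust sandwich variance), which targets
the same prevalence ratios.  Confidence intervals use a PSU-grouped
cluster-robust covariance whenever a cluster column is given.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)

#: Default reference level per covariate (the stratum each PR compares against).
REFERENCE_LEVELS = {
    "age_group": "20-24",
    "ethnicity": "white",
    "literacy": "secondary_or_university",
    "marital_status": "married_or_stable",
    "parity": "multipara",
    "prenatal_band": ">4",
    "risk_exposure": "absent",
    "previous_csection": "absent",
    "labour_onset": "spontaneous",
    "delivery_mode": "vaginal",
    "prev_any": "absent",
}

AGE_BINS = ((10, 19), (20, 24), (25, 29), (30, 34), (35, 55))


@dataclass
class PRResult:
    """Prevalence ratio of one exposure category versus its reference."""

    outcome: str
    variable: str
    category: str
    reference: str
    pr: float
    ci_low: float
    ci_high: float
    n_exposed: int
    n_unexposed: int
    kind: str = "crude"  # "crude" | "adjusted"
    note: str = ""

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        for k in ("pr", "ci_low", "ci_high"):
            v = d[k]
            d[k] = None if (isinstance(v, float) and math.isnan(v)) else float(v)
        return d


def add_derived_bands(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach the categorical bands used as model covariates.

    ``age_group``: 10-19 / 20-24 / 25-29 / 30-34 / 35-55;
    ``prenatal_band``: 0 / 1-4 / >4 visits.
    """
    out = cohort.copy()
    age = cohort["maternal_age"]
    labels = [f"{lo}-{hi}" for lo, hi in AGE_BINS]
    grp = pd.Series(pd.NA, index=cohort.index, dtype="object")
    for (lo, hi), lab in zip(AGE_BINS, labels):
        grp[((age >= lo) & (age <= hi)).fillna(False)] = lab
    out["age_group"] = grp
    visits = cohort["prenatal_visits"]
    band = pd.Series(pd.NA, index=cohort.index, dtype="object")
    band[(visits == 0).fillna(False)] = "0"
    band[((visits >= 1) & (visits <= 4)).fillna(False)] = "1-4"
    band[(visits > 4).fillna(False)] = ">4"
    out["prenatal_band"] = band
    out.attrs = dict(cohort.attrs)
    return out


def crude_pr(
    a: int,
    b: int,
    c: int,
    d: int,
    outcome: str = "",
    variable: str = "",
    category: str = "",
    reference: str = "",
) -> PRResult:
    """Crude prevalence ratio from the 2x2 layout.

    ``a``: outcome & exposed, ``b``: reference group & exposed,
    ``c``: outcome & unexposed, ``d``: reference group & unexposed.
    CI by the Katz log method; with ``c == 0`` (or ``a == 0``) the CI is not
    defined and the PR is reported with a note.
    """
    if a + b <= 0 or c + d <= 0:
        raise ValueError("crude_pr requires exposed and unexposed groups to be non-empty")
    p1 = a / (a + b)
    p0 = c / (c + d)
    pr = math.nan if p0 == 0 else p1 / p0
    res = PRResult(
        outcome=outcome,
        variable=variable,
        category=category,
        reference=reference,
        pr=pr,
        ci_low=math.nan,
        ci_high=math.nan,
        n_exposed=a + b,
        n_unexposed=c + d,
        kind="crude",
    )
    if a == 0 or c == 0:
        res.note = "zero outcome count in one arm: CI not defined"
        return res
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    res.ci_low = pr * math.exp(-Z95 * se)
    res.ci_high = pr * math.exp(Z95 * se)
    return res


def _dummy_design(
    df: pd.DataFrame, covariates: list[str], reference_levels: dict
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Reference-coded dummy design matrix; returns (X, [(var, level, ref)])."""
    cols = {}
    terms = []
    for var in covariates:
        col = df[var]
        if str(col.dtype) == "boolean":
            col = col.map({True: "present", False: "absent"})
        levels = sorted({str(v) for v in col.dropna().unique()})
        ref = str(reference_levels.get(var, levels[0]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from {var!r} (levels: {levels})")
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{var}[{lev}]"] = (col.astype(str) == lev).astype(float)
            terms.append((var, lev, ref))
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "Intercept", 1.0)
    return X, terms


class PrevalenceRatioRegression(BaseEstimator):
    """Adjusted prevalence ratios of one outcome class versus no morbidity.

    Fits ``P(outcome) = exp(Xb)`` on the records belonging to the outcome
    class or the no-morbidity group, complete-case on the model variables.
    The primary family is log-link binomial; on non-convergence (or fitted
    probabilities above 1) the modified-Poisson estimator is used.  With a
    ``cluster_col`` the covariance is the PSU-grouped sandwich.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : list[PRResult]
        One adjusted PR per non-reference covariate level.
    summary_ : pandas.DataFrame
        The same results in tabular form.
    family_used_ : str
        "log-binomial" or "modified-poisson".
    n_obs_ : int
        Complete-case records used in the fit.
    """

    def __init__(
        self,
        outcome: str = "MNM",
        covariates: tuple = ("prev_any",),
        reference_levels: dict | None = None,
        cluster_col: str | None = "cluster_id",
        severity_col: str = "severity",
        tol: float = 1e-8,
        maxiter: int = 100,
    ):
        self.outcome = outcome
        self.covariates = covariates
        self.reference_levels = reference_levels
        self.cluster_col = cluster_col
        self.severity_col = severity_col
        self.tol = tol
        self.maxiter = maxiter

    def fit(self, X: pd.DataFrame, y=None) -> "PrevalenceRatioRegression":
        df = X
        refs = dict(REFERENCE_LEVELS)
        if self.reference_levels:
            refs.update(self.reference_levels)
        sub = df[df[self.severity_col].isin([self.outcome, "NONE"])].copy()
        model_vars = list(self.covariates)
        if self.cluster_col:
            model_vars = model_vars + [self.cluster_col]
        sub = sub.dropna(subset=model_vars)
        if sub.empty:
            raise ValueError("no complete-case records for the requested model")
        yvec = (sub[self.severity_col] == self.outcome).astype(float).to_numpy()
        Xmat, terms = _dummy_design(sub, list(self.covariates), refs)

        groups = None
        if self.cluster_col:
            groups = sub[self.cluster_col].astype(str).to_numpy()
            if len(np.unique(groups)) < 2:
                logger.warning("fewer than 2 clusters: using unclustered variance")
                groups = None

        fit, family_used = self._fit_glm(yvec, Xmat, groups)
        self.family_used_ = family_used
        self.n_obs_ = int(len(sub))
        self.n_clusters_ = int(len(np.unique(groups))) if groups is not None else 1
        # few-PSU sandwich CIs use t(G-1) critical values, as survey software does
        self.crit_ = (
            float(stats.t.ppf(0.975, self.n_clusters_ - 1)) if groups is not None else float(Z95)
        )
        self.params_ = pd.Series(fit.params, index=Xmat.columns)
        self.results_ = self._collect(fit, Xmat, terms, sub)
        self.summary_ = pd.DataFrame([r.to_dict() for r in self.results_])
        return self

    # -- internals ---------------------------------------------------------
    def _fit_glm(self, y, X, groups):
        cov_kw = (
            {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
            if groups is not None
            else {"cov_type": "HC1"}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log()))
                start = np.zeros(X.shape[1])
                start[0] = math.log(max(y.mean(), 1e-6))
                fit = model.fit(start_params=start, maxiter=self.maxiter, tol=self.tol, **cov_kw)
                mu = fit.predict(X)
                if fit.converged and np.all(mu < 1.0):
                    return fit, "log-binomial"
            except Exception as exc:  # fall through to modified Poisson
                logger.info("log-binomial fit failed (%s); using modified Poisson", exc)
            model = sm.GLM(y, X, family=sm.families.Poisson())
            fit = model.fit(maxiter=self.maxiter, tol=self.tol, **cov_kw)
            if not fit.converged:
                raise RuntimeError("modified-Poisson fallback did not converge")
            return fit, "modified-poisson"

    def _collect(self, fit, Xmat, terms, sub):
        params = np.asarray(fit.params)
        se = np.asarray(fit.bse)
        crit = self.crit_
        results = []
        for j, (var, lev, ref) in enumerate(terms, start=1):
            beta, s = params[j], se[j]
            exposed = Xmat.iloc[:, j] == 1.0
            res = PRResult(
                outcome=self.outcome,
                variable=var,
                category=lev,
                reference=ref,
                pr=float(np.exp(beta)),
                ci_low=float(np.exp(beta - crit * s)),
                ci_high=float(np.exp(beta + crit * s)),
                n_exposed=int(exposed.sum()),
                n_unexposed=int((~exposed).sum()),
                kind="adjusted",
            )
            if not np.isfinite(beta) or not np.isfinite(s) or s > 1e3:
                res.pr, res.ci_low, res.ci_high = math.nan, math.nan, math.nan
                res.note = "unstable estimate (possible separation)"
            results.append(res)
        return results


def adjusted_pr(
    classified: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    cluster_col: str | None = "cluster_id",
    reference_levels: dict | None = None,
) -> list[PRResult]:
    """Fit the adjusted-PR model and return one result per covariate level."""
    est = PrevalenceRatioRegression(
        outcome=outcome,
        covariates=tuple(covariates),
        reference_levels=reference_levels,
        cluster_col=cluster_col,
    ).fit(classified)
    return est.results_


def crude_pr_from_cohort(
    classified: pd.DataFrame,
    outcome: str,
    variable: str,
    category: str,
    reference: str,
    severity_col: str = "severity",
) -> PRResult:
    """Crude PR for one exposure category computed from a classified cohort."""
    sub = classified[classified[severity_col].isin([outcome, "NONE"])]
    col = sub[variable]
    if str(col.dtype) == "boolean":
        col = col.map({True: "present", False: "absent"})
    col = col.astype("object")
    is_out = sub[severity_col] == outcome
    a = int(((col == category) & is_out).sum())
    b = int(((col == category) & ~is_out).sum())
    c = int(((col == reference) & is_out).sum())
    d = int(((col == reference) & ~is_out).sum())
    return crude_pr(a, b, c, d, outcome=outcome, variable=variable, category=category, reference=reference)
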