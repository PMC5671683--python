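"""Synthetic perinatal-registry cohorts with known ground truth.

The generator emulates the structure of a multi-country birth registry:
records clustered in country-level primary sampling units, a severity-class
mixture matching the observed morbidity gradient, covariates with
configurable multiplicative (log-prevalence-ratio) effects on each morbidity
class, a class-conditional neonatal near-miss gradient, class-conditional
stillbirth rates, and MCAR missingness at per-field rates.

Default rates are the observed surveillance values: a ~38% any-morbidity
mixture split across the four morbidity classes, 12 clusters, per-field
missingness matching the stratified-table footnotes, and the neonatal
near-miss gradient 4.9/6.4/5.2/14.5/13.1% from no-morbidity up to maternal
death.

Class assignment is an exact multiplicative-risk model: for each non-
reference class ``c``, ``p_c = base_c * exp(sum of covariate effects)`` with
the remainder going to "none", so a configured log-PR is recovered (up to
the small conditioning term) by the prevalence-ratio estimators.  Criterion
flags are then set so the rule-based classifier returns exactly the intended
class, and criterion fields are never masked — ground-truth labels stay
recoverable.  A ``mask_criterion_fields`` switch enables masking everything
for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema
from .schema import FIELDS, LSMM_FLAGS, PLTC_FLAGS, coerce_cohort


class SimConfigError(ValueError):
    """The configuration cannot generate valid probabilities."""


# Observed severity mixture (exact count fractions; sums to 1).
_N_TOTAL = 712_081
DEFAULT_MIXTURE = {
    "MD": 1_028 / _N_TOTAL,
    "MNM": 21_985 / _N_TOTAL,
    "PLTC": 110_038 / _N_TOTAL,
    "LSMM": 137_589 / _N_TOTAL,
    "NONE": 441_441 / _N_TOTAL,
}

# Neonatal near-miss probability per severity class.
DEFAULT_NNM_GRADIENT = {"NONE": 0.049, "LSMM": 0.064, "PLTC": 0.052, "MNM": 0.145, "MD": 0.131}

# Stillbirth (fetal death) rate per severity class.
DEFAULT_STILLBIRTH = {"NONE": 0.019, "LSMM": 0.022, "PLTC": 0.020, "MNM": 0.025, "MD": 0.049}

# Baseline covariate category probabilities (no-morbidity column profile).
DEFAULT_COVARIATE_PREVALENCES = {
    "age_group": {"10-19": 0.2478, "20-24": 0.2935, "25-29": 0.2196, "30-34": 0.1467, "35-55": 0.0924},
    "ethnicity": {"white": 0.2228, "mixed": 0.7300, "other": 0.0472},
    "literacy": {"none_or_primary": 0.4832, "secondary_or_university": 0.5168},
    "marital_status": {"married_or_stable": 0.8667, "single_or_other": 0.1333},
    "parity": {"nullipara": 0.3804, "multipara": 0.6196},
    "prenatal_band": {"0": 0.0765, "1-4": 0.2892, ">4": 0.6343},
    "risk_exposure": {"present": 0.0957, "absent": 0.9043},
    "previous_csection": {"present": 0.1431, "absent": 0.8569},
    "labour_onset": {"spontaneous": 0.8272, "induced": 0.0499, "elective_csection": 0.1229},
    "delivery_mode": {"csection": 0.2846, "vaginal": 0.7154},
    "prev_any": {"present": 0.0351, "absent": 0.9649},
}

# Default covariate effects: history of a previous pathological condition
# raises every morbidity class (log prevalence ratios).
DEFAULT_COVARIATE_EFFECTS = {
    "prev_any": {
        "present": {
            "MD": float(np.log(2.29)),
            "MNM": float(np.log(2.49)),
            "PLTC": float(np.log(1.43)),
            "LSMM": float(np.log(1.52)),
        }
    }
}

# Per-field MCAR missingness (stratified-table footnote rates).
DEFAULT_MISSINGNESS = {
    "maternal_age": 0.004,
    "ethnicity": 0.069,
    "literacy": 0.041,
    "marital_status": 0.042,
    "parity": 0.076,
    "prev_any": 0.124,
    "prenatal_visits": 0.076,
    "risk_exposure": 0.311,
    "previous_csection": 0.168,
    "labour_onset": 0.054,
    "delivery_mode": 0.012,
    "gestational_age_weeks": 0.061,
    "birthweight_g": 0.020,
    "apgar5": 0.030,
    "child_discharge_status": 0.155,
}

CLASS_ORDER = ("MD", "MNM", "PLTC", "LSMM")

# Mechanisms that make the classifier return each class (criterion fields).
MNM_MECHANISMS = ("eclampsia_or_mgso4", "cardiac_disease", "renal_disease", "long_stay", "transfusion_haemorrhage")
PLTC_MECHANISMS = PLTC_FLAGS + ("blood_transfusion",)
LSMM_MECHANISMS = LSMM_FLAGS


@dataclass
class SimConfig:
    """Full description of one synthetic cohort; the seed fixes everything."""

    seed: int = 0
    n_records: int = 20_000
    n_clusters: int = 12
    cluster_sizes: tuple | None = None  # explicit sizes override n_records/n_clusters
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    covariate_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()})
    covariate_prevalences: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PREVALENCES.items()})
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    neonatal_gradient: dict = field(default_factory=lambda: dict(DEFAULT_NNM_GRADIENT))
    stillbirth_rate: dict = field(default_factory=lambda: dict(DEFAULT_STILLBIRTH))
    cluster_effect_sd: float = 0.0  # sd of per-cluster log shift on morbidity classes
    covariate_cluster_sd: float = 0.0  # sd of per-cluster log shift on covariate prevalences
    mask_criterion_fields: bool = False  # "realistic" switch: also mask criterion flags

    def validate(self) -> None:
        mix = self.class_mixture
        if set(mix) != set(schema.SEVERITY_LEVELS):
            raise SimConfigError(f"class_mixture must cover {schema.SEVERITY_LEVELS}")
        if any(p < 0 or p > 1 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise SimConfigError("class_mixture must be probabilities summing to 1")
        for rates in (self.missingness_rates, self.neonatal_gradient, self.stillbirth_rate):
            if any(p < 0 or p > 1 for p in rates.values()):
                raise SimConfigError("all probabilities must lie in [0, 1]")
        for var, prevs in self.covariate_prevalences.items():
            if abs(sum(prevs.values()) - 1.0) > 1e-6:
                raise SimConfigError(f"category probabilities for {var!r} must sum to 1")
        # worst-case feasibility of the multiplicative class model
        worst = 0.0
        for c in CLASS_ORDER:
            mult = 1.0
            for var, cats in self.covariate_effects.items():
                if var not in self.covariate_prevalences:
                    raise SimConfigError(f"effects reference unknown covariate {var!r}")
                mult *= max([np.exp(eff.get(c, 0.0)) for eff in cats.values()] + [1.0])
            worst += mix[c] * mult
        if worst > 1.0:
            raise SimConfigError(
                f"infeasible covariate effects: worst-case morbidity probability {worst:.3f} > 1"
            )


def _draw_categorical(rng, prevs: dict, n: int) -> np.ndarray:
    cats = list(prevs)
    p = np.asarray([prevs[c] for c in cats], dtype=float)
    return np.asarray(cats, dtype=object)[rng.choice(len(cats), size=n, p=p / p.sum())]


def _generate(config: SimConfig):
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.cluster_sizes is not None:
        sizes = [int(s) for s in config.cluster_sizes]
        n = int(sum(sizes))
        cluster = np.repeat([f"C{k:02d}" for k in range(len(sizes))], sizes)
    else:
        n = int(config.n_records)
        cluster = np.asarray([f"C{k:02d}" for k in range(config.n_clusters)], dtype=object)[
            rng.integers(0, config.n_clusters, size=n)
        ]
    n_clusters = len(np.unique(cluster))

    cov = _draw_covariates(rng, config, cluster, n)

    # per-record class probabilities: base * exp(effects) * cluster shift
    log_shift = np.zeros(n)
    if config.cluster_effect_sd > 0:
        shifts = {c: rng.normal(0.0, config.cluster_effect_sd) for c in np.unique(cluster)}
        log_shift = np.asarray([shifts[c] for c in cluster])
    probs = np.zeros((n, len(CLASS_ORDER)))
    for j, cls in enumerate(CLASS_ORDER):
        with np.errstate(divide="ignore"):  # a zero mixture weight is a valid degenerate config
            logp = np.full(n, np.log(config.class_mixture[cls]))
        for var, cats in config.covariate_effects.items():
            for cat, eff in cats.items():
                e = eff.get(cls, 0.0)
                if e:
                    logp += np.where(cov[var] == cat, e, 0.0)
        probs[:, j] = np.exp(logp + log_shift)
    total = probs.sum(axis=1)
    if np.any(total > 1.0):
        raise SimConfigError(
            f"infeasible configuration: {int((total > 1).sum())} records with morbidity probability > 1"
        )
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n)
    true_class = np.full(n, "NONE", dtype=object)
    assigned = np.zeros(n, dtype=bool)
    for j, cls in enumerate(CLASS_ORDER):
        take = ~assigned & (u < cum[:, j])
        true_class[take] = cls
        assigned |= take

    df = pd.DataFrame({name: pd.Series([pd.NA] * n, dtype="object") for name in FIELDS})
    df["record_id"] = [f"r{i:06d}" for i in range(n)]
    df["cluster_id"] = cluster

    # covariates
    df["maternal_age"] = _age_from_band(rng, cov["age_group"])
    df["ethnicity"] = cov["ethnicity"]
    df["literacy"] = cov["literacy"]
    df["marital_status"] = cov["marital_status"]
    df["parity"] = cov["parity"]
    df["prenatal_visits"] = _visits_from_band(rng, cov["prenatal_band"])
    df["risk_exposure"] = cov["risk_exposure"] == "present"
    df["previous_csection"] = cov["previous_csection"] == "present"
    df["labour_onset"] = cov["labour_onset"]
    df["delivery_mode"] = cov["delivery_mode"]
    prev_any = cov["prev_any"] == "present"
    for flag in schema.PREVIOUS_FLAGS:
        df[flag] = False
    df["prev_any"] = prev_any
    df["prev_hypertension"] = prev_any  # one concrete history condition keeps prev_any consistent

    # criterion fields: defaults that satisfy no rule
    for flag in schema.MNM_FLAGS + PLTC_FLAGS + LSMM_FLAGS:
        df[flag] = False
    df["hospital_stay_days"] = rng.integers(1, 6, size=n)
    df["death_status"] = "alive"
    _set_class_mechanisms(rng, df, true_class)

    # neonatal outcomes
    stillbirth_p = np.asarray([config.stillbirth_rate[c] for c in true_class])
    fetal_death = rng.random(n) < stillbirth_p
    df["vital_status_at_birth"] = np.where(fetal_death, "fetal_death", "live")
    nnm_p = np.asarray([config.neonatal_gradient[c] for c in true_class])
    nnm = rng.random(n) < nnm_p
    _set_neonatal(rng, df, nnm)
    true_nnm = pd.array(nnm, dtype="boolean")
    true_nnm[fetal_death] = pd.NA

    disc = rng.random(n)
    df["child_discharge_status"] = np.select(
        [disc < 0.980, disc < 0.990], ["alive", "neonatal_death"], default="referred"
    )
    df.loc[fetal_death, "child_discharge_status"] = pd.NA

    truth = pd.DataFrame(
        {
            "record_id": df["record_id"].to_numpy(),
            "cluster_id": cluster,
            "true_class": true_class,
            "true_nnm": true_nnm,
            **{f"true_{var}": cov[var] for var in config.covariate_effects},
        }
    )

    _apply_missingness(rng, df, config)
    return coerce_cohort(df), truth


def _draw_covariates(rng, config: SimConfig, cluster: np.ndarray, n: int) -> dict:
    """Draw covariate categories; with ``covariate_cluster_sd`` > 0 the
    category prevalences get an independent log-scale shift per cluster,
    inducing between-PSU covariate heterogeneity."""
    if config.covariate_cluster_sd <= 0:
        return {var: _draw_categorical(rng, prevs, n) for var, prevs in config.covariate_prevalences.items()}
    cov: dict = {}
    cluster_ids = np.unique(cluster)
    for var, prevs in config.covariate_prevalences.items():
        cats = list(prevs)
        base = np.log(np.asarray([max(prevs[c], 1e-12) for c in cats]))
        out = np.empty(n, dtype=object)
        for cid in cluster_ids:
            rows = cluster == cid
            logp = base + rng.normal(0.0, config.covariate_cluster_sd, size=len(cats))
            p = np.exp(logp)
            p /= p.sum()
            out[rows] = np.asarray(cats, dtype=object)[rng.choice(len(cats), size=int(rows.sum()), p=p)]
        cov[var] = out
    return cov


def _age_from_band(rng, band: np.ndarray) -> np.ndarray:
    lo = np.select([band == "10-19", band == "20-24", band == "25-29", band == "30-34"], [10, 20, 25, 30], 35)
    hi = np.select([band == "10-19", band == "20-24", band == "25-29", band == "30-34"], [19, 24, 29, 34], 55)
    return rng.integers(lo, hi + 1)


def _visits_from_band(rng, band: np.ndarray) -> np.ndarray:
    v = rng.integers(5, 13, size=len(band))
    v = np.where(band == "0", 0, v)
    return np.where(band == "1-4", rng.integers(1, 5, size=len(band)), v)


def _set_class_mechanisms(rng, df: pd.DataFrame, true_class: np.ndarray) -> None:
    """Set criterion fields so the default classifier returns the intended class."""
    md = true_class == "MD"
    if md.any():
        df.loc[md, "death_status"] = np.where(
            rng.random(md.sum()) < 0.8, "died_at_facility", "died_in_transport_or_referral"
        )
    for cls, mechanisms in [("MNM", MNM_MECHANISMS), ("MD", MNM_MECHANISMS)]:
        rows = np.flatnonzero(true_class == cls)
        if not len(rows):
            continue
        mech = rng.choice(len(mechanisms), size=len(rows))
        for m, name in enumerate(mechanisms):
            idx = df.index[rows[mech == m]]
            if name == "long_stay":
                df.loc[idx, "hospital_stay_days"] = rng.integers(8, 22, size=len(idx))
            elif name == "transfusion_haemorrhage":
                df.loc[idx, "blood_transfusion"] = True
                df.loc[idx, "haemorrhage_any"] = True
            else:
                df.loc[idx, name] = True
    for cls, mechanisms in [("PLTC", PLTC_MECHANISMS), ("LSMM", LSMM_MECHANISMS)]:
        rows = np.flatnonzero(true_class == cls)
        if not len(rows):
            continue
        mech = rng.choice(len(mechanisms), size=len(rows))
        for m, name in enumerate(mechanisms):
            df.loc[df.index[rows[mech == m]], name] = True
    # co-occurring lower-grade morbidity (precedence keeps the label intact)
    upper = np.isin(true_class, ("MD", "MNM", "PLTC"))
    extra = upper & (rng.random(len(true_class)) < 0.5)
    if extra.any():
        lsmm_extra = rng.choice(len(LSMM_FLAGS), size=int(extra.sum()))
        for m, name in enumerate(LSMM_FLAGS):
            df.loc[df.index[np.flatnonzero(extra)[lsmm_extra == m]], name] = True


def _set_neonatal(rng, df: pd.DataFrame, nnm: np.ndarray) -> None:
    n = len(df)
    ga = np.round(rng.uniform(37.0, 41.5, size=n), 1)
    bw = np.round(np.clip(rng.normal(3250.0, 400.0, size=n), 2500, 4500))
    apgar = rng.integers(8, 11, size=n)
    which = rng.integers(0, 3, size=n)  # qualifying component for near-miss newborns
    ga = np.where(nnm & (which == 0), np.round(rng.uniform(26.0, 32.5, size=n), 1), ga)
    bw = np.where(nnm & (which == 1), np.round(rng.uniform(900.0, 1740.0, size=n)), bw)
    apgar = np.where(nnm & (which == 2), rng.integers(0, 7, size=n), apgar)
    df["gestational_age_weeks"] = ga
    df["birthweight_g"] = bw
    df["apgar5"] = apgar


# Fields that must never be masked so truth stays recoverable.
PROTECTED_FIELDS = frozenset(
    {"record_id", "cluster_id", "death_status", "hospital_stay_days", "vital_status_at_birth"}
    | set(schema.MNM_FLAGS)
    | set(PLTC_FLAGS)
    | set(LSMM_FLAGS)
)


def _apply_missingness(rng, df: pd.DataFrame, config: SimConfig) -> None:
    for fname, rate in config.missingness_rates.items():
        if fname not in FIELDS or rate <= 0:
            continue
        if fname in PROTECTED_FIELDS and not config.mask_criterion_fields:
            continue
        mask = rng.random(len(df)) < rate
        if fname == "prev_any":  # keep the any/component invariant decidable
            for col in schema.PREVIOUS_FLAGS:
                _mask_column(df, col, mask)
        else:
            _mask_column(df, fname, mask)
    if config.mask_criterion_fields:
        for fname in PROTECTED_FIELDS - {"record_id", "cluster_id"}:
            mask = rng.random(len(df)) < config.missingness_rates.get(fname, 0.03)
            _mask_column(df, fname, mask)


def _mask_column(df: pd.DataFrame, name: str, mask: np.ndarray) -> None:
    col = df[name].astype("object")
    col[mask] = pd.NA
    df[name] = col


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a schema-valid cohort; the seed fully determines the output."""
    cohort, _ = _generate(config)
    return cohort


def truth_table(config: SimConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Ground truth (intended class, neonatal near miss, exposure values) for
    a cohort produced by :func:`generate_cohort` with the same config."""
    regen, truth = _generate(config)
    if len(regen) != len(cohort) or not regen.reset_index(drop=True).equals(
        cohort[regen.columns].reset_index(drop=True)
    ):
        raise ValueError("cohort does not match the supplied configuration")
    return truth
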