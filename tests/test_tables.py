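"""Stratified tables and the design-effect-corrected chi-square."""

import math

import numpy as np
import pandas as pd
import pytest

from matgrade.classifier import classify_cohort
from matgrade.simulate import SimConfig, generate_cohort, truth_table
from matgrade.tables import build_table, crosstab, rao_scott_chi2

from conftest import blank_record, cohort_from_records


def _pearson_by_hand(tab: np.ndarray) -> float:
    """Closed-form Pearson chi-square, independent of the implementation."""
    tab = np.asarray(tab, dtype=float)
    n = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    return float(((tab - expected) ** 2 / expected).sum())


def test_crosstab_single_cell_holds_everyone():
    recs = [blank_record() for _ in range(7)]
    classified = classify_cohort(cohort_from_records(recs))
    table = crosstab(classified, "anaemia")
    assert table.counts.shape == (1, 1)
    assert int(table.counts.iloc[0, 0]) == 7
    assert table.missing_fraction == 0.0


def test_crosstab_balanced_symmetry():
    recs = []
    for i in range(40):
        recs.append(blank_record(anaemia=(i % 2 == 0), hiv_positive=(i % 4 < 2)))
    classified = classify_cohort(cohort_from_records(recs))
    # all records are LSMM; hiv_positive splits evenly within the class
    table = crosstab(classified, "hiv_positive")
    assert (table.counts.to_numpy() == 20).all() or table.counts.to_numpy().sum() == 40


def test_crosstab_reports_missing_fraction():
    recs = [blank_record(ethnicity=None) for _ in range(3)] + [blank_record() for _ in range(7)]
    classified = classify_cohort(cohort_from_records(recs))
    table = crosstab(classified, "ethnicity")
    assert table.missing_fraction == pytest.approx(0.3)
    assert table.counts.to_numpy().sum() == 7


def test_crosstab_unknown_variable_errors(default_cohort):
    classified = classify_cohort(default_cohort)
    with pytest.raises(ValueError, match="unknown variable"):
        crosstab(classified, "not_a_field")


def test_single_cluster_equals_pearson_oracle():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 2, 400)
    y = rng.integers(0, 2, 400)
    res = rao_scott_chi2(x, y, np.zeros(400))
    tab = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    assert res["chi2_corrected"] == pytest.approx(_pearson_by_hand(tab), rel=1e-12)
    assert res["design_effect"] == 1.0
    assert "single cluster" in res["note"]


def test_known_2x2_single_cluster_p_value():
    # counts (10,20;30,40) laid out as record-level data
    x = np.repeat([0, 0, 1, 1], [30, 40, 10, 20])
    y = np.repeat([0, 1, 0, 1], [30, 40, 10, 20])
    res = rao_scott_chi2(x, y, np.zeros(100))
    chi2 = _pearson_by_hand(np.array([[10, 20], [30, 40]]))
    from scipy.stats import chi2 as chi2_dist

    assert res["chi2_corrected"] == pytest.approx(chi2, rel=1e-12)
    assert res["p_corrected"] == pytest.approx(float(chi2_dist.sf(chi2, 1)), rel=1e-12)


def test_corrected_not_larger_when_design_effect_above_one():
    cfg = SimConfig(seed=31, n_records=12_000, cluster_effect_sd=0.2)
    classified = classify_cohort(generate_cohort(cfg))
    table = build_table(classified, "prev_any")
    assert table.n_clusters == 12
    assert table.design_effect >= 1.0  # strong induced between-country heterogeneity
    assert table.chi2_corrected <= table.chi2_uncorrected
    assert 0.0 <= table.p_corrected <= 1.0


def test_degenerate_table_flagged_not_crashed():
    res = rao_scott_chi2(np.zeros(50), np.repeat([0, 1], 25), np.repeat([0, 1], 25))
    assert math.isnan(res["chi2_corrected"])
    assert "degenerate" in res["note"]


def test_corrected_type_one_error_not_above_uncorrected_under_heterogeneity():
    """With strong between-cluster heterogeneity under the null association,
    the corrected test rejects no more often than the uncorrected one."""
    rng = np.random.default_rng(77)
    rej_c = rej_u = 0
    reps = 300
    from scipy.stats import chi2 as chi2_dist

    for _ in range(reps):
        n_clusters, size = 12, 60
        clu = np.repeat(np.arange(n_clusters), size)
        # cluster-level shifts hit both variables -> correlated within PSU, no true link
        shift = rng.normal(0, 1.2, n_clusters)[clu]
        x = (rng.random(len(clu)) < 1 / (1 + np.exp(-shift))).astype(int)
        y = (rng.random(len(clu)) < 1 / (1 + np.exp(-shift + rng.normal(0, 0.3, len(clu))))).astype(int)
        res = rao_scott_chi2(x, y, clu)
        if math.isnan(res["chi2_uncorrected"]):
            continue
        rej_c += res["p_corrected"] < 0.05
        rej_u += chi2_dist.sf(res["chi2_uncorrected"], res["df"]) < 0.05
    assert rej_c <= rej_u
    assert rej_u > reps * 0.3  # the uncorrected test is badly anticonservative here


def test_neonatal_gradient_recovered_in_table():
    cfg = SimConfig(seed=41, n_records=60_000)
    cohort = generate_cohort(cfg)
    truth = truth_table(cfg, cohort)
    classified = classify_cohort(cohort)
    table = crosstab(classified, "neonatal_near_miss")
    for lvl, p in cfg.neonatal_gradient.items():
        n_class = int(truth["true_class"].eq(lvl).sum())
        if n_class < 200:
            continue  # too few deaths for a stable rate at this n
        col = table.counts[lvl]
        frac = col.get(True, 0) / col.sum()
        se = math.sqrt(p * (1 - p) / col.sum())
        assert abs(frac - p) < 4 * se, lvl
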