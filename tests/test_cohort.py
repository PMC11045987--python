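"""Cohort arm: quartiles, log transform, logistic models, subgroups."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, strategies as hs

import cohortmr as cm
from cohortmr.cohort import build_design
from conftest import make_2x2


# ---------------------------------------------------------------------------
# quartiles
# ---------------------------------------------------------------------------

def test_quartiles_1_to_8():
    labels, cuts = cm.assign_quartiles(np.arange(1.0, 9.0))
    assert cuts == (2.75, 4.5, 6.25)
    assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_quartiles_ties_go_lower():
    vals = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    labels, cuts = cm.assign_quartiles(vals)
    # values equal to a cutpoint land in the lower quartile
    at_cut = np.isclose(vals, cuts[0])
    assert all(l == "Q1" for l, a in zip(labels, at_cut) if a)


def test_quartiles_errors():
    with pytest.raises(cm.DegenerateQuartileError):
        cm.assign_quartiles([2.0] * 10)
    with pytest.raises(cm.EmptyInputError):
        cm.assign_quartiles([np.nan, np.nan])
    with pytest.raises(cm.DomainError):
        cm.assign_quartiles([1.0, 2.0, 3.0])


def test_quartile_count_conservation(cohort_default):
    table, _ = cohort_default
    labels, _ = cm.assign_quartiles(table["cystatin_c"])
    assert labels.notna().sum() == table["cystatin_c"].notna().sum()
    assert labels.value_counts().sum() == len(table)


def test_quartile_cutpoints_near_printed_ranges(cohort_default):
    # the default exposure law was fit to the printed quartile boundaries
    table, _ = cohort_default
    _, cuts = cm.assign_quartiles(table["cystatin_c"])
    assert abs(cuts[0] - 0.85) < 0.02
    assert abs(cuts[2] - 1.11) < 0.02


# ---------------------------------------------------------------------------
# log transform + K-S
# ---------------------------------------------------------------------------

def test_log_exposure_constant_degenerate():
    logged, report = cm.log_exposure([3.0] * 10)
    assert np.allclose(logged, np.log(3.0))
    assert report.degenerate


def test_log_exposure_rejects_nonpositive():
    with pytest.raises(cm.DomainError):
        cm.log_exposure([1.0, 0.0, 2.0])


def test_log_improves_normality_of_lognormal():
    wins = 0
    for seed in range(30):
        x = np.exp(np.random.default_rng(seed).normal(0, 0.3, 5000))
        _, rep = cm.log_exposure(x)
        wins += rep.p_log > rep.p_raw
    assert wins >= 27


def test_exp_standard_normal_passes_ks_after_log():
    passes = 0
    for seed in range(30):
        x = np.exp(np.random.default_rng(1000 + seed).standard_normal(2000))
        _, rep = cm.log_exposure(x)
        passes += rep.p_log > 0.01
    assert passes >= 27


# ---------------------------------------------------------------------------
# logistic fits
# ---------------------------------------------------------------------------

def test_unadjusted_or_equals_cross_product():
    # Q4 vs Q1 stroke/total layout: 206/1,557 vs 129/1,640
    table = make_2x2(1557, 206, 1640, 129)
    fit = cm.fit_logistic(table, exposure_spec="none", adjustment="none",
                          extra_columns={"exposed": table["exposed"]})
    cross = (206 / 1351) / (129 / 1511)
    assert abs(fit.or_table.loc["exposed", "OR"] - cross) / cross < 1e-6


def test_null_model_z_statistics(small_cohort):
    table, _ = small_cohort
    rng = np.random.default_rng(5)
    shuffled = table.copy()
    shuffled["stroke"] = rng.permutation(table["stroke"].to_numpy())
    fit = cm.fit_logistic(shuffled, "quartile", "model2")
    assert (fit.or_table["p"] > 0.001).mean() > 0.8


def test_missing_category_policy_adds_levels(small_cohort):
    table, _ = small_cohort
    fit = cm.fit_logistic(table, "quartile", "model2", "category")
    assert fit.n_used == len(table)
    assert "smoking[missing]" in fit.coefficients.index
    assert "glucose_missing" in fit.coefficients.index
    cc = cm.fit_logistic(table, "quartile", "model2", "complete-case")
    assert cc.n_used < len(table)
    assert "smoking[missing]" not in cc.coefficients.index


def test_nested_model_consistency(small_cohort):
    # Model 2 with every extra coefficient pinned to zero is Model 1
    table, _ = small_cohort
    y, X2, _ = build_design(table, "quartile", "model2", "category")
    m1_terms = [c for c in X2.columns if c.startswith(("Q", "age_group", "sex"))
                or c == "const"]
    import statsmodels.api as sm
    res = sm.GLM(y, X2[m1_terms], family=sm.families.Binomial()).fit()
    fit1 = cm.fit_logistic(table, "quartile", "model1", "category")
    assert abs(np.exp(res.params["Q4"]) - fit1.or_table.loc["Q4", "OR"]) < 1e-8


def test_constant_shift_of_continuous_covariate(small_cohort):
    table, _ = small_cohort
    shifted = table.copy()
    shifted["glucose"] = shifted["glucose"] + 10.0
    f0 = cm.fit_logistic(table, "quartile", "model2", "complete-case")
    f1 = cm.fit_logistic(shifted, "quartile", "model2", "complete-case")
    keep = [t for t in f0.coefficients.index if t != "const"]
    np.testing.assert_allclose(f0.coefficients[keep], f1.coefficients[keep],
                               atol=1e-6)
    assert abs(f0.coefficients["const"] - f1.coefficients["const"]) > 1e-3


def test_separation_raises():
    table = make_2x2(50, 50, 50, 0)
    with pytest.raises(cm.SeparationError):
        cm.fit_logistic(table, exposure_spec="none", adjustment="none",
                        extra_columns={"exposed": table["exposed"]})


def test_or_table_consistency(cohort_default):
    table, _ = cohort_default
    fit = cm.fit_logistic(table, "quartile", "model1")
    for term in fit.or_table.index:
        beta = fit.coefficients[term]
        row = fit.or_table.loc[term]
        assert abs(np.exp(beta) - row["OR"]) <= 1e-10 * row["OR"]
        assert row["lower95"] <= row["OR"] <= row["upper95"]


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

def test_subgroup_sex_runs_and_interaction_terms(cohort_default):
    table, _ = cohort_default
    res = cm.subgroup_analysis(table, "sex")
    assert set(res.per_stratum) == {"male", "female"}
    assert set(res.interaction_p) == {"Q2", "Q3", "Q4"}
    for fit in res.per_stratum.values():
        assert "sex[female]" not in fit.coefficients.index


def test_subgroup_interaction_power():
    # a +1.0 log-OR sex-by-exposure interaction should be detectable
    hits = 0
    for seed in range(5):
        cfg = cm.CohortConfig(n_participants=20000, seed=seed,
                              interaction_effects={"sex=female": (0, 1.0, 1.0, 1.0)})
        table, _ = cm.generate_cohort(cfg)
        res = cm.subgroup_analysis(table, "sex", adjustment="model1")
        hits += min(res.interaction_p.values()) < 0.05
    assert hits >= 4


def test_subgroup_interaction_null_calibration():
    sig = 0
    for seed in range(30):
        table, _ = cm.generate_cohort(cm.CohortConfig(n_participants=4000, seed=seed))
        res = cm.subgroup_analysis(table, "sex", adjustment="model1")
        sig += res.interaction_p["Q4"] < 0.05
    assert sig <= 6  # ~5% nominal


def test_single_level_stratifier_errors(small_cohort):
    table, _ = small_cohort
    mono = table.copy()
    mono["sex"] = "female"
    with pytest.raises(cm.InputError):
        cm.subgroup_analysis(mono, "sex")


def test_baseline_table_shape(cohort_default):
    table, _ = cohort_default
    bt = cm.baseline_table(table)
    assert list(bt.columns) == ["Overall", "Q1", "Q2", "Q3", "Q4"]
    assert bt.loc["Participants, N", "Overall"] == str(len(table))
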