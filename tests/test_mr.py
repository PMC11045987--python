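"""MR engine: selection, clumping, harmonization, Wald/IVW/Egger/PRESSO."""

import numpy as np
import pandas as pd
import pytest

import cohortmr as cm
from cohortmr.io import LDReference
from cohortmr.mr import HarmonizedSet


def _sumstats(rows):
    return pd.DataFrame(rows, columns=["snp", "chr", "pos", "effect_allele",
                                       "other_allele", "eaf", "beta", "se",
                                       "pval", "n"])


def _hset(bx, sx, by, sy):
    n = len(bx)
    frame = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "beta_exp": bx, "se_exp": sx, "eaf_exp": 0.3,
        "beta_out": by, "se_out": sy, "eaf_out": 0.3,
    })
    return HarmonizedSet(frame, pd.DataFrame())


# ---------------------------------------------------------------------------
# instrument selection and clumping
# ---------------------------------------------------------------------------

def test_select_strict_threshold():
    df = _sumstats([("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000),
                    ("rs2", 1, 200, "A", "G", 0.3, 0.1, 0.01, 5e-8, 1000),
                    ("rs3", 1, 300, "A", "G", 0.3, 0.1, 0.01, 4.9e-8, 1000)])
    kept = cm.mr.select_instruments(df)
    assert list(kept["snp"]) == ["rs1", "rs3"]
    empty = cm.mr.select_instruments(df.assign(pval=0.5))
    assert empty.empty


def test_clump_keeps_most_significant_of_linked_pair():
    df = _sumstats([("rs1", 1, 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
                    ("rs2", 1, 2000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)])
    ld = LDReference([("rs1", "rs2", 0.5)])
    assert cm.mr.ld_clump(df, ld) == ["rs1"]


def test_clump_cross_chromosome_ignores_spurious_r2():
    df = _sumstats([("rs1", 1, 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
                    ("rs2", 2, 1000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)])
    ld = LDReference([("rs1", "rs2", 0.9)])
    assert set(cm.mr.ld_clump(df, ld)) == {"rs1", "rs2"}


def test_clump_all_independent_retained():
    rows = [(f"rs{i}", 1, 1000 + i * 20_000_000, "A", "G", 0.3, 0.1, 0.01,
             1e-9, 1000) for i in range(10)]
    assert len(cm.mr.ld_clump(_sumstats(rows), LDReference())) == 10


def test_clump_outside_window_retained_despite_high_r2():
    df = _sumstats([("rs1", 1, 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
                    ("rs2", 1, 1000 + 10_001_000, "A", "G", 0.3, 0.1, 0.01,
                     1e-9, 1000)])
    ld = LDReference([("rs1", "rs2", 0.9)])
    assert set(cm.mr.ld_clump(df, ld)) == {"rs1", "rs2"}


def test_malformed_ld_triplet_rejected():
    with pytest.raises(cm.InputError):
        LDReference([("rs1", "rs2", 1.5)])


# ---------------------------------------------------------------------------
# harmonization rule table
# ---------------------------------------------------------------------------

def _one_pair(ea_e, oa_e, ea_o, oa_o, eaf_e=0.3, eaf_o=0.3, b_out=0.05):
    exp = _sumstats([("rs1", 1, 100, ea_e, oa_e, eaf_e, 0.1, 0.01, 1e-9, 1000)])
    out = _sumstats([("rs1", 1, 100, ea_o, oa_o, eaf_o, b_out, 0.02, 0.01, 2000)])
    return cm.mr.harmonize(exp, out)


@pytest.mark.parametrize("alleles,expected_action,expected_beta", [
    (("A", "G", "A", "G"), "unchanged", 0.05),
    (("A", "G", "G", "A"), "allele-swap", -0.05),
    (("A", "G", "T", "C"), "strand-flip", 0.05),       # complement, same order
    (("A", "G", "C", "T"), "allele-swap", -0.05),      # complement + swap
    (("A", "G", "A", "C"), "dropped-incompatible", None),
])
def test_harmonize_rule_table(alleles, expected_action, expected_beta):
    h = _one_pair(*alleles)
    assert h.audit["action_taken"].iloc[0] == expected_action
    if expected_beta is None:
        assert len(h) == 0
    else:
        assert h.frame["beta_out"].iloc[0] == pytest.approx(expected_beta)


def test_harmonize_palindromic_rules():
    # ambiguous frequency (0.5): dropped
    h = _one_pair("A", "T", "A", "T", eaf_e=0.5, eaf_o=0.5)
    assert h.audit["action_taken"].iloc[0] == "dropped-palindromic"
    assert len(h) == 0
    # informative, concordant frequency: kept unchanged
    h = _one_pair("A", "T", "A", "T", eaf_e=0.2, eaf_o=0.22)
    assert h.audit["action_taken"].iloc[0] == "unchanged"
    # informative, discordant frequency: strand flip (sign change)
    h = _one_pair("A", "T", "A", "T", eaf_e=0.2, eaf_o=0.78)
    assert h.audit["action_taken"].iloc[0] == "strand-flip"
    assert h.frame["beta_out"].iloc[0] == pytest.approx(-0.05)


def test_harmonize_duplicate_id_rejected():
    exp = _sumstats([("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000),
                     ("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)])
    out = _sumstats([("rs1", 1, 100, "A", "G", 0.3, 0.05, 0.02, 0.01, 2000)])
    with pytest.raises(cm.InputError):
        cm.mr.harmonize(exp, out)


def test_orientation_invariance(gwas_default):
    # flipping one SNP's alleles in BOTH studies leaves estimates unchanged
    exposure, outcome, ld, _ = gwas_default
    exp2, out2 = exposure.copy(), outcome.copy()
    for df in (exp2, out2):
        df.loc[0, ["effect_allele", "other_allele"]] = \
            df.loc[0, ["other_allele", "effect_allele"]].to_numpy()
        df.loc[0, "beta"] = -df.loc[0, "beta"]
        df.loc[0, "eaf"] = 1 - df.loc[0, "eaf"]
    e1 = cm.mr.ivw(cm.mr.harmonize(exposure, outcome))
    e2 = cm.mr.ivw(cm.mr.harmonize(exp2, out2))
    assert e1.beta == pytest.approx(e2.beta, abs=1e-12)
    s1, i1 = cm.mr.egger(cm.mr.harmonize(exposure, outcome))
    s2, i2 = cm.mr.egger(cm.mr.harmonize(exp2, out2))
    assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
    assert i1["estimate"] == pytest.approx(i2["estimate"], abs=1e-12)


# ---------------------------------------------------------------------------
# Wald ratio and IVW
# ---------------------------------------------------------------------------

def test_wald_ratio_basic_and_limits():
    est, se = cm.mr.wald_ratio(0.1, 0.01, 0.05, 0.02)
    assert est == pytest.approx(0.5)
    est1, se1 = cm.mr.wald_ratio(0.1, 0.0, 0.05, 0.02)
    assert se1 == pytest.approx(0.02 / 0.1)
    with pytest.raises(cm.DomainError):
        cm.mr.wald_ratio(0.0, 0.01, 0.05, 0.02)


def test_wald_se_matches_monte_carlo():
    _, se = cm.mr.wald_ratio(0.1, 0.01, 0.05, 0.02)
    rng = np.random.default_rng(123)
    draws = rng.normal(0.05, 0.02, 10**6) / rng.normal(0.1, 0.01, 10**6)
    assert abs(se - draws.std()) / draws.std() < 0.02


def test_ivw_single_instrument_is_wald_ratio():
    h = _hset([0.1], [0.01], [0.05], [0.02])
    est = cm.mr.ivw(h)
    w_est, w_se = cm.mr.wald_ratio(0.1, 0.01, 0.05, 0.02)
    assert est.beta == pytest.approx(float(w_est))
    assert est.se == pytest.approx(float(w_se))
    assert est.extra["Q"] is None


def test_ivw_identical_ratios_q_zero():
    h = _hset([0.1, 0.2, 0.05], [0.0, 0.0, 0.0],
              [0.05, 0.10, 0.025], [0.02, 0.04, 0.01])
    rand = cm.mr.ivw(h, model="random")
    fixed = cm.mr.ivw(h, model="fixed")
    assert rand.extra["Q"] == pytest.approx(0.0, abs=1e-20)
    assert rand.se == pytest.approx(fixed.se)
    assert rand.beta == pytest.approx(0.5)


def test_ivw_empty_errors():
    with pytest.raises(cm.EmptyInputError):
        cm.mr.ivw(_hset([], [], [], []))


def test_ivw_equals_zero_intercept_wls_with_first_order_weights(harmonized_default):
    h, _ = harmonized_default
    est = cm.mr.ivw(h, model="fixed", se_order=1)
    f = h.frame
    w = 1 / f["se_out"] ** 2
    slope = np.sum(w * f["beta_exp"] * f["beta_out"]) / np.sum(w * f["beta_exp"] ** 2)
    assert est.beta == pytest.approx(float(slope), rel=1e-8)


def test_ivw_or_ci_consistency(harmonized_default):
    h, _ = harmonized_default
    est = cm.mr.ivw(h)
    assert est.or_ == pytest.approx(np.exp(est.beta), rel=1e-12)
    lo, hi = est.ci95
    assert lo < est.or_ < hi


# ---------------------------------------------------------------------------
# Egger
# ---------------------------------------------------------------------------

def test_egger_exact_proportional_points():
    bx = np.array([0.05, 0.08, 0.11, 0.06])
    h = _hset(bx, np.full(4, 0.005), 0.3 * bx, np.full(4, 0.02))
    slope, intercept = cm.mr.egger(h)
    assert intercept["estimate"] == pytest.approx(0.0, abs=1e-12)
    assert slope.beta == pytest.approx(0.3, abs=1e-12)


def test_egger_needs_three_instruments():
    with pytest.raises(cm.InsufficientInstrumentsError):
        cm.mr.egger(_hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.02, 0.02]))


def test_egger_reduces_to_ivw_without_intercept(harmonized_default):
    # zero-intercept WLS with 1/se_out^2 weights == IVW with first-order SEs
    h, _ = harmonized_default
    f = h.frame
    w = 1 / f["se_out"] ** 2
    slope = np.sum(w * f["beta_exp"] * f["beta_out"]) / np.sum(w * f["beta_exp"] ** 2)
    est = cm.mr.ivw(h, model="fixed", se_order=1)
    assert est.beta == pytest.approx(float(slope), rel=1e-10)


def test_egger_balanced_pleiotropy_intercept_near_zero():
    covered = 0
    for seed in range(40):
        e, o, ld, tr = cm.generate_gwas_pair(cm.GwasSimConfig(
            seed=3000 + seed, n_instruments=100, pleiotropy_mode="balanced"))
        slope, inter = cm.mr.egger(cm.mr.harmonize(e, o))
        covered += abs(inter["estimate"]) < 1.96 * inter["se"]
    assert covered >= 34


def test_egger_directional_pleiotropy_power():
    hits = 0
    for seed in range(20):
        e, o, ld, tr = cm.generate_gwas_pair(cm.GwasSimConfig(
            seed=4000 + seed, pleiotropy_mode="directional",
            pleiotropy_mean=0.02))
        slope, inter = cm.mr.egger(cm.mr.harmonize(e, o))
        hits += inter["p"] < 0.05
    assert hits >= 16


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def test_presso_needs_four_instruments():
    with pytest.raises(cm.InsufficientInstrumentsError):
        cm.mr.mr_presso(_hset([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.02] * 3))


def test_presso_deterministic(harmonized_default):
    h, _ = harmonized_default
    a = cm.mr.mr_presso(h, n_sim=300, seed=9)
    b = cm.mr.mr_presso(h, n_sim=300, seed=9)
    assert a.global_p == b.global_p
    assert a.outliers == b.outliers


def test_presso_no_outliers_corrected_equals_raw(harmonized_default):
    h, _ = harmonized_default
    res = cm.mr.mr_presso(h, n_sim=300, seed=2)
    if not res.outliers:
        assert res.corrected.beta == res.raw.beta
        assert res.distortion_p is None


def test_presso_flags_planted_outliers():
    e, o, ld, tr = cm.generate_gwas_pair(cm.GwasSimConfig(seed=5, n_outliers=3))
    h = cm.mr.harmonize(cm.mr.select_instruments(e), o)
    res = cm.mr.mr_presso(h, seed=11)
    assert set(res.outliers) == set(tr["outlier_snps"])
    assert res.global_p < 0.05
    truth = tr["true_causal_effect"]
    assert abs(res.corrected.beta - truth) < abs(res.raw.beta - truth)
    assert res.distortion_p is not None
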