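"""Two-sample Mendelian randomization engine.

Pipeline: select genome-wide-significant instruments (p < 5e-8), greedily
LD-clump them (r2 < 0.001 within a 10,000-kb window), harmonize outcome
effects to the exposure's effect allele, form per-SNP Wald ratios with
delta-method SEs, and pool by random-effects inverse-variance weighting
(multiplicative overdispersion) with Cochran's Q.  MR-Egger regression
probes directional pleiotropy via its intercept, and MR-PRESSO detects and
removes pleiotropic outlier instruments via a simulated residual-sum-of-
squares null (global, outlier and distortion tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import (
    DomainError,
    EmptyInputError,
    InputError,
    InsufficientInstrumentsError,
)
from .io import LDReference

_Z975 = st.norm.ppf(0.975)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def select_instruments(exposure: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Retain SNPs with p strictly below the genome-wide threshold.

    Input row order is preserved.
    """
    return exposure.loc[exposure["pval"] < p_threshold].copy()


def ld_clump(snps: pd.DataFrame, ld: LDReference, r2_threshold: float = 0.001,
             window_kb: float = 10000) -> list[str]:
    """Greedy LD clumping.

    SNPs are visited in ascending p-value order (stable for ties); a SNP is
    accepted iff no previously accepted SNP on the same chromosome lies
    within ``window_kb`` kilobases AND has r2 >= ``r2_threshold`` with it.
    Returns retained SNP ids in the input table's row order.
    """
    for col in ("snp", "chr", "pos", "pval"):
        if col not in snps.columns:
            raise InputError(f"clumping input lacks column {col}")
    order = snps.sort_values("pval", kind="mergesort")
    accepted: list[tuple[str, int, int]] = []
    kept: set[str] = set()
    window = window_kb * 1000.0
    for _, row in order.iterrows():
        ok = True
        for aid, achr, apos in accepted:
            if row["chr"] == achr and abs(row["pos"] - apos) <= window \
                    and ld.r2(row["snp"], aid) >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append((row["snp"], row["chr"], row["pos"]))
            kept.add(row["snp"])
    return [s for s in snps["snp"] if s in kept]


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedSet:
    """Instruments with outcome effects aligned to the exposure effect allele.

    ``frame`` holds retained instruments (snp, beta_exp, se_exp, eaf_exp,
    beta_out, se_out, eaf_out); ``audit`` records every intersected SNP with
    the ``action_taken`` label.
    """
    frame: pd.DataFrame
    audit: pd.DataFrame

    def __len__(self):
        return len(self.frame)


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_eaf_limit: float = 0.42) -> HarmonizedSet:
    """Align outcome records to the exposure's effect allele.

    Matching alleles pass unchanged; swapped effect/other alleles flip the
    outcome beta sign (and eaf); strand-complement records are complemented
    and re-compared. Palindromic (A/T, C/G) SNPs are label-aligned first and
    then orientation-checked by allele frequency: if either study's
    min(eaf, 1-eaf) >= ``palindromic_eaf_limit`` the frequency is
    uninformative and the SNP is dropped; a discordant frequency after label
    alignment indicates a strand flip and the outcome beta is flipped.
    Irreconcilable allele pairs are dropped.
    """
    for df, label in ((exposure, "exposure"), (outcome, "outcome")):
        if df["snp"].duplicated().any():
            raise InputError(f"duplicate SNP id within the {label} study")
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    if merged.empty:
        raise EmptyInputError("no shared SNPs between exposure and outcome")

    rows, audit = [], []
    for _, r in merged.iterrows():
        ea_e, oa_e = r["effect_allele_exp"], r["other_allele_exp"]
        ea_o, oa_o = r["effect_allele_out"], r["other_allele_out"]
        b_out, eaf_out = float(r["beta_out"]), float(r["eaf_out"])
        action = None

        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                action = "dropped-incompatible"
            else:
                if ea_o != ea_e:           # label swap first
                    b_out, eaf_out = -b_out, 1.0 - eaf_out
                    action = "allele-swap"
                else:
                    action = "unchanged"
                ambiguous = (min(r["eaf_exp"], 1 - r["eaf_exp"]) >= palindromic_eaf_limit
                             or min(eaf_out, 1 - eaf_out) >= palindromic_eaf_limit)
                if ambiguous:
                    action = "dropped-palindromic"
                elif (r["eaf_exp"] - 0.5) * (eaf_out - 0.5) < 0:
                    # frequencies disagree after label alignment: strand flip
                    b_out, eaf_out = -b_out, 1.0 - eaf_out
                    action = "strand-flip"
        else:
            if (ea_o, oa_o) == (ea_e, oa_e):
                action = "unchanged"
            elif (ea_o, oa_o) == (oa_e, ea_e):
                b_out, eaf_out = -b_out, 1.0 - eaf_out
                action = "allele-swap"
            else:
                cea, coa = _COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)
                if (cea, coa) == (ea_e, oa_e):
                    action = "strand-flip"
                elif (cea, coa) == (oa_e, ea_e):
                    b_out, eaf_out = -b_out, 1.0 - eaf_out
                    action = "allele-swap"
                else:
                    action = "dropped-incompatible"

        audit.append((r["snp"], action))
        if not action.startswith("dropped"):
            rows.append((r["snp"], float(r["beta_exp"]), float(r["se_exp"]),
                         float(r["eaf_exp"]), b_out, float(r["se_out"]), eaf_out))

    frame = pd.DataFrame(rows, columns=["snp", "beta_exp", "se_exp", "eaf_exp",
                                        "beta_out", "se_out", "eaf_out"])
    audit_df = pd.DataFrame(audit, columns=["snp", "action_taken"])
    return HarmonizedSet(frame, audit_df)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - _Z975 * self.se)),
                float(np.exp(self.beta + _Z975 * self.se)))


def wald_ratio(beta_exp, se_exp, beta_out, se_out, order: int = 2):
    """Per-instrument causal estimate beta_out/beta_exp with delta-method SE.

    ``order=2`` (default) uses the second-order expansion
    sqrt(se_out^2/beta_exp^2 + beta_out^2 * se_exp^2 / beta_exp^4);
    ``order=1`` uses se_out/|beta_exp|.
    """
    beta_exp = np.asarray(beta_exp, dtype=float)
    if np.any(beta_exp == 0):
        raise DomainError("Wald ratio undefined for beta_exp = 0")
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    se_exp = np.asarray(se_exp, dtype=float)
    est = beta_out / beta_exp
    if order == 2:
        se = np.sqrt(se_out ** 2 / beta_exp ** 2
                     + beta_out ** 2 * se_exp ** 2 / beta_exp ** 4)
    elif order == 1:
        se = se_out / np.abs(beta_exp)
    else:
        raise DomainError("delta-method order must be 1 or 2")
    return est, se


def _ratios(h: HarmonizedSet, se_order: int):
    f = h.frame
    return wald_ratio(f["beta_exp"].to_numpy(), f["se_exp"].to_numpy(),
                      f["beta_out"].to_numpy(), f["se_out"].to_numpy(),
                      order=se_order)


def ivw(h: HarmonizedSet, model: str = "random", se_order: int = 2) -> MREstimate:
    """Inverse-variance-weighted pooling of Wald ratios with Cochran's Q.

    The random-effects model inflates the pooled SE by
    sqrt(max(1, Q/(n-1))) (multiplicative overdispersion).  With a single
    instrument the estimate is its Wald ratio and Q is undefined.
    """
    n = len(h)
    if n == 0:
        raise EmptyInputError("no instruments for IVW")
    theta, se = _ratios(h, se_order)
    if n == 1:
        est, pse = float(theta[0]), float(se[0])
        q = q_p = None
    else:
        w = 1.0 / se ** 2
        est = float(np.sum(w * theta) / np.sum(w))
        pse = float(np.sqrt(1.0 / np.sum(w)))
        q = float(np.sum(w * (theta - est) ** 2))
        q_p = float(st.chi2.sf(q, n - 1))
        if model == "random":
            pse *= float(np.sqrt(max(1.0, q / (n - 1))))
        elif model != "fixed":
            raise InputError(f"unknown IVW model {model!r}")
    p = float(2 * st.norm.sf(abs(est / pse))) if pse > 0 else float(est == 0.0)
    return MREstimate("IVW", est, pse, p, n,
                      extra={"Q": q, "Q_df": None if q is None else n - 1, "Q_p": q_p,
                             "model": model})


def egger(h: HarmonizedSet, se_order: int = 2) -> tuple[MREstimate, dict]:
    """MR-Egger weighted regression; returns (slope estimate, intercept record).

    Outcome betas are regressed on exposure betas with a free intercept,
    weights 1/se_out^2, after orienting every instrument so beta_exp > 0.
    SEs carry multiplicative overdispersion floored at 1; p-values use a t
    distribution with n-2 df.  A nonzero intercept flags directional
    pleiotropy.
    """
    n = len(h)
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    f = h.frame
    sign = np.sign(f["beta_exp"].to_numpy())
    bx = f["beta_exp"].to_numpy() * sign
    by = f["beta_out"].to_numpy() * sign
    w = 1.0 / f["se_out"].to_numpy() ** 2

    X = np.column_stack([np.ones(n), bx])
    XtW = X.T * w
    cov_u = np.linalg.inv(XtW @ X)
    coef = cov_u @ (XtW @ by)
    resid = by - X @ coef
    phi = max(1.0, float(np.sum(w * resid ** 2) / (n - 2)))
    cov = cov_u * phi
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * st.t.sf(np.abs(tvals), n - 2)
    slope = MREstimate("Egger-slope", float(coef[1]), float(se[1]),
                       float(pvals[1]), n, extra={"overdispersion": phi})
    intercept = {"estimate": float(coef[0]), "se": float(se[0]), "p": float(pvals[0])}
    return slope, intercept


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outliers: list[str]
    outlier_p: pd.Series
    raw: MREstimate
    corrected: MREstimate
    distortion_p: float | None


def _loo_slopes(bx, by, w):
    """Leave-one-out zero-intercept WLS slopes of by on bx."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, alpha: float = 0.05,
              seed: int = 0, n_distortion: int = 1000,
              se_order: int = 1) -> PressoResult:
    """Pleiotropy residual sum and outlier test.

    Raw and corrected estimates default to first-order (regression-scale)
    Wald weights, matching the 1/se_out^2 weighting of the RSS machinery
    itself; second-order weights would let an outlier's own inflated
    outcome effect shrink its weight, inconsistently with the simulated
    null.

    Global test: the observed weighted RSS of leave-one-out IVW predictions
    is referred to a parametric null of ``n_sim`` simulated datasets drawn
    under the no-pleiotropy model (p with the (1+#exceed)/(1+n_sim)
    estimator).  Outlier test: each SNP's observed RSS term is referred to
    its simulated null summarised as a scaled chi-square(1) tail, Bonferroni-
    corrected at ``alpha``.  The corrected estimate is the IVW estimate on
    the non-outlier instruments; the distortion test compares the observed
    estimate shift against shifts from removing random same-size subsets.
    """
    n = len(h)
    if n < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 instruments")
    rng = np.random.default_rng(seed)
    f = h.frame
    bx = f["beta_exp"].to_numpy(float)
    by = f["beta_out"].to_numpy(float)
    sx = f["se_exp"].to_numpy(float)
    sy = f["se_out"].to_numpy(float)
    w = 1.0 / sy ** 2

    slope_loo = _loo_slopes(bx, by, w)
    rss_i = w * (by - slope_loo * bx) ** 2
    rss_obs = float(np.sum(rss_i))

    BX = bx + rng.normal(0.0, sx, size=(n_sim, n))
    BY = slope_loo * bx + rng.normal(0.0, sy, size=(n_sim, n))
    sxx_s = np.sum(w * BX * BX, axis=1, keepdims=True)
    sxy_s = np.sum(w * BX * BY, axis=1, keepdims=True)
    slope_s = (sxy_s - w * BX * BY) / (sxx_s - w * BX * BX)
    rss_si = w * (BY - slope_s * BX) ** 2
    rss_s = rss_si.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (1 + n_sim))

    # per-SNP tail: simulated null summarised as scale * chi2(1)
    scale = rss_si.mean(axis=0)
    outlier_p = pd.Series(st.chi2.sf(rss_i / scale, df=1), index=f["snp"].to_numpy())
    flags = outlier_p < alpha / n
    outliers = list(outlier_p.index[flags])

    raw = ivw(h, model="random", se_order=se_order)
    keep = ~f["snp"].isin(outliers)
    corrected_h = HarmonizedSet(f.loc[keep].reset_index(drop=True), h.audit)
    corrected = ivw(corrected_h, model="random", se_order=se_order)
    corrected = MREstimate("PRESSO-corrected", corrected.beta, corrected.se,
                           corrected.p, corrected.n_snps, corrected.extra)

    distortion_p = None
    k = len(outliers)
    if 0 < k < n:
        theta, se_t = wald_ratio(bx, sx, by, sy, order=se_order)
        wt = 1.0 / se_t ** 2
        sw, swt = float(np.sum(wt)), float(np.sum(wt * theta))
        obs_change = corrected.beta - raw.beta
        changes = np.empty(n_distortion)
        for b in range(n_distortion):
            drop = rng.choice(n, size=k, replace=False)
            est_b = (swt - np.sum(wt[drop] * theta[drop])) / (sw - np.sum(wt[drop]))
            changes[b] = est_b - raw.beta
        distortion_p = float((1 + np.sum(np.abs(changes) >= abs(obs_change)))
                             / (1 + n_distortion))

    return PressoResult(rss_obs, global_p, outliers, outlier_p, raw,
                        corrected, distortion_p)
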