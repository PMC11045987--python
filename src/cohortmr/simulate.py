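"""Synthetic study-shaped data.

Two generators make every downstream stage testable without any external
download:

* :func:`generate_cohort` draws a participant-level table shaped like a
  middle-aged/older national cohort: log-normal serum cystatin C (mg/L), a
  binary incident-stroke outcome whose logit is a per-exposure-quartile
  baseline plus optional covariate effects, the usual covariate roster
  (demographics, lifestyle, comorbidity, lipids/glucose/hs-CRP/creatinine),
  and completely-at-random missingness injected per covariate.

* :func:`generate_gwas_pair` draws matched exposure/outcome GWAS
  summary-statistics tables for a configurable number of independent
  instruments, with a known causal effect, configurable horizontal
  pleiotropy (none/balanced/directional), plantable outlier SNPs, allele
  bookkeeping noise (effect/other swaps, strand flips, palindromic SNPs)
  to exercise harmonization, and a pairwise LD reference.

Both generators are pure functions of their config (seed included) and emit
a ground-truth sidecar for use as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CATEGORICAL_LEVELS, QUARTILE_LABELS, assign_quartiles
from .errors import ConfigurationError
from .io import LDReference

# marginal level probabilities for the categorical covariates, matching the
# descriptive profile of the emulated cohort (rural-majority, ~46% male,
# mostly married, low education, ~43% hypertensive, ~18% diabetic)
CATEGORICAL_MARGINALS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "sex": (("male", "female"), (0.461, 0.539)),
    "residence": (("rural", "urban"), (0.804, 0.196)),
    "education": (("primary", "secondary", "third"), (0.687, 0.200, 0.113)),
    "marital": (("married", "others"), (0.882, 0.118)),
    "smoking": (("never", "former", "current"), (0.600, 0.070, 0.330)),
    "drinking": (("no", "yes"), (0.653, 0.347)),
    "bmi_group": (("<23.9", "24-27.9", ">=28"), (0.565, 0.212, 0.223)),
    "hypertension": (("no", "yes"), (0.574, 0.426)),
    "diabetes": (("no", "yes"), (0.816, 0.184)),
    "fasting": (("no", "yes"), (0.10, 0.90)),
}


@dataclass
class CohortConfig:
    """Conditions for one synthetic cohort draw.

    ``quartile_risk`` are the target incidence probabilities per exposure
    quartile (defaults mirror a 7.9/9.4/9.4/13.2% gradient over n=6,501 with
    ~10% overall incidence). ``covariate_effects`` maps covariate names
    (binary/continuous) or ``"column=level"`` keys to log-odds added to the
    outcome logit; continuous covariates are centred at their generated mean
    so the quartile baselines stay calibrated. ``interaction_effects`` maps
    ``"column=level"`` keys to four per-quartile extra log-odds.
    ``exposure_lognormal_params`` are (mu, sigma) of log cystatin C; the
    defaults put the empirical quartile cuts near 0.85/0.97/1.11 mg/L.
    """
    n_participants: int = 6501
    quartile_risk: tuple[float, float, float, float] = (0.079, 0.094, 0.094, 0.132)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    exposure_lognormal_params: tuple[float, float] = (-0.0305, 0.198)
    interaction_effects: Mapping[str, Sequence[float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 8:
            raise ConfigurationError("n_participants must be >= 8 for nonempty quartiles")
        if len(self.quartile_risk) != 4 or not all(0 < p < 1 for p in self.quartile_risk):
            raise ConfigurationError("quartile_risk must be four probabilities in (0,1)")
        for name, r in self.missing_rates.items():
            if not (0 <= r < 1):
                raise ConfigurationError(f"missing rate for {name!r} must be in [0,1)")
        if self.exposure_lognormal_params[1] <= 0:
            raise ConfigurationError("exposure log-sigma must be positive")
        for key, vals in self.interaction_effects.items():
            if len(vals) != 4:
                raise ConfigurationError(
                    f"interaction_effects[{key!r}] needs one value per quartile")


def _effect_column(df: pd.DataFrame, key: str) -> np.ndarray:
    """Numeric per-row contribution multiplier for one effect key."""
    if "=" in key:
        col, level = key.split("=", 1)
        return (df[col].to_numpy() == level).astype(float)
    if key in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[key]
        if len(levels) != 2:
            raise ConfigurationError(
                f"covariate_effects[{key!r}]: multi-level categorical needs "
                f"'column=level' syntax")
        return (df[key].to_numpy() == levels[1]).astype(float)
    x = df[key].to_numpy(dtype=float)
    return x - x.mean()


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort table; returns (table, truth sidecar)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    mu, sigma = config.exposure_lognormal_params

    log_cys = rng.normal(mu, sigma, n)
    cys = np.exp(log_cys)
    z = (log_cys - mu) / sigma

    df = pd.DataFrame({"cystatin_c": cys})
    # age correlates with the exposure (renal function declines with age)
    age = 59.6 + 4.5 * z + rng.normal(0.0, 8.4, n)
    df["age"] = np.clip(age, 45.0, 100.0).round(1)
    df["age_group"] = pd.cut(df["age"], [0, 65, 85, np.inf], right=False,
                             labels=["<65", "65-84", ">=85"]).astype(object)
    for name, (levels, probs) in CATEGORICAL_MARGINALS.items():
        df[name] = rng.choice(levels, size=n, p=probs)
    df["triglyceride"] = np.exp(rng.normal(0.28, 0.45, n)).round(3)
    df["non_hdl"] = np.clip(rng.normal(3.45, 0.95, n), 0.8, None).round(3)
    df["glucose"] = np.clip(rng.normal(5.9, 1.5, n), 2.5, None).round(3)
    df["hs_crp"] = np.exp(rng.normal(0.0, 1.0, n)).round(3)
    # creatinine shares the renal-function signal with cystatin C
    df["creatinine"] = np.exp(np.log(0.75) + 0.55 * sigma * z
                              + rng.normal(0.0, 0.14, n)).round(3)

    labels, cuts = assign_quartiles(df["cystatin_c"])
    q_index = labels.map({q: i for i, q in enumerate(QUARTILE_LABELS)}).to_numpy(int)
    base = logit(config.quartile_risk[0])
    q_logor = np.array([logit(p) - base for p in config.quartile_risk])

    eta = base + q_logor[q_index]
    for key, coef in config.covariate_effects.items():
        eta = eta + coef * _effect_column(df, key)
    for key, per_q in config.interaction_effects.items():
        eta = eta + np.asarray(per_q, dtype=float)[q_index] * _effect_column(df, key)
    df["stroke"] = (rng.random(n) < expit(eta)).astype(int)

    # MCAR missingness, covariates only
    for name, rate in config.missing_rates.items():
        if name in ("stroke", "cystatin_c"):
            raise ConfigurationError("outcome and exposure are never made missing")
        if name not in df.columns:
            raise ConfigurationError(f"unknown covariate in missing_rates: {name!r}")
        mask = rng.random(n) < rate
        df.loc[mask, name] = np.nan

    truth = {
        "quartile_risk": list(config.quartile_risk),
        "quartile_logor": q_logor.tolist(),
        "quartile_cutpoints": list(cuts),
        "covariate_effects": dict(config.covariate_effects),
        "interaction_effects": {k: list(v) for k, v in config.interaction_effects.items()},
        "exposure_lognormal_params": list(config.exposure_lognormal_params),
        "seed": config.seed,
    }
    return df, truth


# ---------------------------------------------------------------------------
# GWAS summary-statistics pair
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class GwasSimConfig:
    """Conditions for one exposure/outcome summary-statistics pair.

    Defaults emulate a 223-instrument exposure GWAS of 363,228 individuals
    against a stroke GWAS of 40,585 cases / 406,111 controls, with a true
    causal log-OR per SD exposure of ln(1.114). Per-SNP exposure effects are
    uniform on ``beta_exposure_range`` (effect allele oriented
    exposure-increasing) with SE = 1/sqrt(2*maf*(1-maf)*n). Outcome SEs use
    the effective case/control sample size. ``n_outliers`` SNPs receive
    directional pleiotropy of ``outlier_scale`` (>=10) times the outcome SE.
    ``swap_fraction``/``flip_fraction`` control how many outcome records are
    stored effect/other-swapped or strand-complemented;
    ``palindromic_fraction`` of SNPs get A/T or C/G alleles.
    """
    n_instruments: int = 223
    beta_exposure_range: tuple[float, float] = (0.04, 0.12)
    true_causal_effect: float = float(np.log(1.114))
    pleiotropy_mode: str = "none"            # none | balanced | directional
    pleiotropy_mean: float = 0.02            # directional mode
    pleiotropy_sd: float = 0.02              # balanced / directional spread
    n_outliers: int = 0
    outlier_scale: float = 12.0
    n_exposure: int = 363228
    n_outcome_cases: int = 40585
    n_outcome_controls: int = 406111
    maf_range: tuple[float, float] = (0.10, 0.50)
    palindromic_fraction: float = 0.10
    swap_fraction: float = 0.25
    flip_fraction: float = 0.10
    n_proxy_clusters: int = 0
    proxies_per_cluster: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_instruments < 1:
            raise ConfigurationError("need at least one instrument")
        if self.n_outliers > self.n_instruments:
            raise ConfigurationError("n_outliers cannot exceed n_instruments")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.outlier_scale < 10:
            raise ConfigurationError("outlier pleiotropy must be >= 10x the noise scale")
        for frac in (self.palindromic_fraction, self.swap_fraction, self.flip_fraction):
            if not (0 <= frac <= 1):
                raise ConfigurationError("fractions must lie in [0, 1]")


def _positions(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome/position grid spacing independent SNPs >10 Mb apart."""
    idx = np.arange(n)
    chrom = (idx % 22) + 1
    pos = 1_000_000 + (idx // 22) * 20_000_000
    return chrom, pos


def generate_gwas_pair(config: GwasSimConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame, LDReference, dict]:
    """Draw (exposure SumStats, outcome SumStats, LDReference, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_instruments

    maf = rng.uniform(*config.maf_range, n)
    bx_true = rng.uniform(*config.beta_exposure_range, n)
    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exposure)
    n_eff = 4.0 / (1.0 / config.n_outcome_cases + 1.0 / config.n_outcome_controls)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_eff)

    alpha = np.zeros(n)
    if config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, n)
    elif config.pleiotropy_mode == "directional":
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n)
    outlier_idx = rng.choice(n, size=config.n_outliers, replace=False) \
        if config.n_outliers else np.array([], dtype=int)
    alpha[outlier_idx] = rng.uniform(config.outlier_scale,
                                     config.outlier_scale + 4.0,
                                     len(outlier_idx)) * se_y[outlier_idx]

    bx_hat = bx_true + rng.normal(0.0, se_x)
    by_true = config.true_causal_effect * bx_true + alpha
    by_hat = by_true + rng.normal(0.0, se_y)

    ids = np.array([f"rs{1000 + i}" for i in range(n)])
    chrom, pos = _positions(n)

    # allele bookkeeping
    palindromic = rng.random(n) < config.palindromic_fraction
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), n)
    npal_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), n)
    ea = np.where(palindromic,
                  [_PALINDROMIC_PAIRS[i][0] for i in pal_choice],
                  [_NONPALINDROMIC_PAIRS[i][0] for i in npal_choice])
    oa = np.where(palindromic,
                  [_PALINDROMIC_PAIRS[i][1] for i in pal_choice],
                  [_NONPALINDROMIC_PAIRS[i][1] for i in npal_choice])
    # palindromic SNPs keep eaf away from 0.5 so frequency can orient them
    eaf = maf.copy()
    eaf[palindromic] = np.clip(eaf[palindromic], None, 0.35)

    from scipy.stats import norm
    pval_x = 2 * norm.sf(np.abs(bx_hat / se_x))
    pval_y = np.clip(2 * norm.sf(np.abs(by_hat / se_y)), 1e-300, 1.0)

    exposure = pd.DataFrame({
        "snp": ids, "chr": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": bx_hat, "se": se_x, "pval": np.clip(pval_x, 1e-300, 1.0),
        "n": config.n_exposure,
    })

    out_ea, out_oa = ea.copy(), oa.copy()
    out_beta, out_eaf = by_hat.copy(), np.clip(
        eaf + rng.normal(0.0, 0.005, n), 0.01, 0.99)
    swapped = rng.random(n) < config.swap_fraction
    out_ea[swapped], out_oa[swapped] = oa[swapped], ea[swapped]
    out_beta[swapped] *= -1.0
    out_eaf[swapped] = 1.0 - out_eaf[swapped]
    flipped = (rng.random(n) < config.flip_fraction) & ~palindromic
    out_ea[flipped] = [_COMPLEMENT[b] for b in out_ea[flipped]]
    out_oa[flipped] = [_COMPLEMENT[b] for b in out_oa[flipped]]

    outcome = pd.DataFrame({
        "snp": ids, "chr": chrom, "pos": pos,
        "effect_allele": out_ea, "other_allele": out_oa, "eaf": out_eaf,
        "beta": out_beta, "se": se_y, "pval": pval_y,
        "n": config.n_outcome_cases + config.n_outcome_controls,
    })

    # proxy clusters: correlated, slightly weaker neighbours that clumping
    # must remove
    proxy_rows_x, proxy_rows_y, proxy_ld, proxy_ids = [], [], [], []
    if config.n_proxy_clusters:
        parents = rng.choice(n, size=min(config.n_proxy_clusters, n), replace=False)
        next_id = 1000 + n
        for pi in parents:
            for _ in range(config.proxies_per_cluster):
                pid = f"rs{next_id}"
                next_id += 1
                off = int(rng.integers(1_000, 100_000))
                attn = rng.uniform(0.85, 0.97)
                bx_p = bx_hat[pi] * attn
                by_p = by_hat[pi] * attn
                proxy_rows_x.append((pid, chrom[pi], pos[pi] + off, ea[pi], oa[pi],
                                     eaf[pi], bx_p, se_x[pi],
                                     float(np.clip(2 * norm.sf(abs(bx_p / se_x[pi])),
                                                   1e-300, 1.0)),
                                     config.n_exposure))
                proxy_rows_y.append((pid, chrom[pi], pos[pi] + off, ea[pi], oa[pi],
                                     eaf[pi], by_p, se_y[pi],
                                     float(np.clip(2 * norm.sf(abs(by_p / se_y[pi])),
                                                   1e-300, 1.0)),
                                     config.n_outcome_cases + config.n_outcome_controls))
                proxy_ld.append((ids[pi], pid, float(rng.uniform(0.3, 0.95))))
                proxy_ids.append(pid)
        if proxy_rows_x:
            exposure = pd.concat(
                [exposure, pd.DataFrame(proxy_rows_x, columns=exposure.columns)],
                ignore_index=True)
            outcome = pd.concat(
                [outcome, pd.DataFrame(proxy_rows_y, columns=outcome.columns)],
                ignore_index=True)

    ld = LDReference()
    all_ids = exposure["snp"].to_numpy()
    m = len(all_ids)
    if m > 1:
        background = rng.uniform(0.0, 1e-4, m * (m - 1) // 2)
        k = 0
        for i in range(m):
            for j in range(i + 1, m):
                ld.set(all_ids[i], all_ids[j], background[k])
                k += 1
    for a, b, r2 in proxy_ld:
        ld.set(a, b, r2)

    truth = {
        "true_causal_effect": config.true_causal_effect,
        "outlier_snps": [str(ids[i]) for i in sorted(outlier_idx)],
        "instrument_snps": [str(s) for s in ids],
        "proxy_snps": proxy_ids,
        "pleiotropy": {str(ids[i]): float(alpha[i]) for i in range(n)},
        "beta_exposure_true": {str(ids[i]): float(bx_true[i]) for i in range(n)},
        "seed": config.seed,
    }
    return exposure, outcome, ld, truth
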