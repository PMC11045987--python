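"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing covariates (outcome and exposure must be complete) are filled by
``m`` independent chained-equation chains: continuous targets by Bayesian
linear-regression draws (coefficients and residual variance sampled from
their approximate posterior), categorical targets by multinomial logistic
models sampled from predicted class probabilities. Each chain burns in for
``sweeps`` full passes before its completed table is taken. The analysis
model is then fitted once per completed table and the coefficient estimates
are pooled by Rubin's rules with the Barnard-Rubin small-sample degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.linear_model import LogisticRegression

from .cohort import (
    ADJUSTMENTS,
    CATEGORICAL_LEVELS,
    CONTINUOUS_COVARIATES,
    FitResult,
    fit_logistic,
)
from .errors import ConfigurationError, InputError


def _encode_predictors(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Numeric design from the given columns (one-hot for categoricals)."""
    blocks = [np.ones((len(df), 1))]
    for c in cols:
        if c in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[c]
            for lev in levels[1:]:
                blocks.append((df[c].to_numpy() == lev).astype(float)[:, None])
        else:
            blocks.append(pd.to_numeric(df[c], errors="coerce")
                          .to_numpy(float)[:, None])
    return np.hstack(blocks)


def _draw_continuous(rng, X_obs, y_obs, X_mis):
    n, p = X_obs.shape
    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta
    dof = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2 = sigma2_hat * dof / rng.chisquare(dof)
    XtX = X_obs.T @ X_obs
    cov = sigma2 * np.linalg.pinv(XtX)
    # symmetric square root (pinv can leave tiny asymmetries)
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None))) @ vecs.T
    beta_draw = beta + root @ rng.standard_normal(p)
    return X_mis @ beta_draw + rng.normal(0.0, np.sqrt(sigma2), len(X_mis))


def _draw_categorical(rng, X_obs, y_obs, X_mis, levels):
    observed_levels = pd.unique(y_obs)
    if len(observed_levels) < 2:
        return np.repeat(observed_levels[0], len(X_mis))
    model = LogisticRegression(max_iter=500)
    model.fit(X_obs[:, 1:], y_obs)       # sklearn adds its own intercept
    proba = model.predict_proba(X_mis[:, 1:])
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(X_mis))
    idx = (u[:, None] > cum).sum(axis=1)
    return model.classes_[idx]


def impute(table: pd.DataFrame, m: int = 5, seed: int = 0,
           sweeps: int = 10, columns: list[str] | None = None) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of the table (covariates imputed)."""
    if m < 2:
        raise ConfigurationError("multiple imputation needs m >= 2")
    if table["stroke"].isna().any() or table["cystatin_c"].isna().any():
        raise InputError("outcome and exposure must be non-missing before imputation")

    roster = [c for c in (*CATEGORICAL_LEVELS, *CONTINUOUS_COVARIATES)
              if c in table.columns]
    if columns is None:
        columns = [c for c in roster if table[c].isna().any()]
    for c in columns:
        frac = table[c].isna().mean()
        if frac > 0.9:
            raise InputError(f"column {c!r} is {frac:.0%} missing; refusing to impute")
    if not columns:
        return [table.copy() for _ in range(m)]

    base = table.copy()
    base["_log_cys"] = np.log(base["cystatin_c"].astype(float))
    masks = {c: table[c].isna() for c in columns}
    completed = []
    root = np.random.SeedSequence(seed)
    for chain_seq in root.spawn(m):
        rng = np.random.default_rng(chain_seq)
        work = base.copy()
        # initial fill: random draws from the observed margin
        for c in columns:
            obs = work.loc[~masks[c], c].to_numpy()
            work.loc[masks[c], c] = rng.choice(obs, size=int(masks[c].sum()))
        for _ in range(sweeps):
            for c in columns:
                predictors = [p for p in roster if p != c] + ["stroke", "_log_cys"]
                X = _encode_predictors(work, predictors)
                mis = masks[c].to_numpy()
                if c in CATEGORICAL_LEVELS:
                    drawn = _draw_categorical(rng, X[~mis],
                                              work.loc[~masks[c], c].to_numpy(),
                                              X[mis], CATEGORICAL_LEVELS[c])
                else:
                    drawn = _draw_continuous(
                        rng, X[~mis],
                        work.loc[~masks[c], c].to_numpy(float), X[mis])
                work.loc[masks[c], c] = drawn
        completed.append(work.drop(columns=["_log_cys"]))
    return completed


def pool_rubin(estimates, variances, df_com: float = np.inf) -> dict:
    """Rubin's rules for ``m`` point estimates and within-imputation variances.

    Returns pooled estimate, within/between/total variance, Barnard-Rubin
    degrees of freedom, a t-based 95% CI and two-sided p-value.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if estimates.shape != variances.shape:
        raise InputError("estimates and variances must have equal length")
    m = len(estimates)
    if m < 2:
        raise ConfigurationError("pooling needs m >= 2")
    if np.any(variances <= 0):
        raise InputError("within-imputation variances must be positive")

    qbar = float(estimates.mean())
    within = float(variances.mean())
    between = float(estimates.var(ddof=1))
    total = within + (1 + 1 / m) * between

    if between == 0:
        df = np.inf
    else:
        r = (1 + 1 / m) * between / within
        df_old = (m - 1) * (1 + 1 / r) ** 2
        lam = (1 + 1 / m) * between / total
        if np.isfinite(df_com):
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    tcrit = st.t.ppf(0.975, df) if np.isfinite(df) else st.norm.ppf(0.975)
    se = np.sqrt(total)
    tstat = qbar / se if se > 0 else np.inf * np.sign(qbar)
    if np.isfinite(df):
        p = float(2 * st.t.sf(abs(tstat), df))
    else:
        p = float(2 * st.norm.sf(abs(tstat)))
    return {
        "estimate": qbar, "within_var": within, "between_var": between,
        "total_var": total, "df": float(df),
        "ci95": (qbar - tcrit * se, qbar + tcrit * se), "p": p,
    }


@dataclass
class ImputationResult:
    completed_tables: list
    per_imputation_fits: list
    pooled: pd.DataFrame          # per term: estimate, vars, df, CI, p, OR


def impute_and_pool(table: pd.DataFrame, m: int = 5, seed: int = 0,
                    sweeps: int = 10, exposure_spec: str = "quartile",
                    adjustment: str = "model2") -> ImputationResult:
    """Impute, refit the analysis model per completed table, pool by Rubin."""
    tables = impute(table, m=m, seed=seed, sweeps=sweeps)
    fits = [fit_logistic(t, exposure_spec, adjustment,
                         missing_policy="complete-case") for t in tables]
    terms = [t for t in fits[0].coefficients.index if t != "const"]
    rows = {}
    for term in terms:
        ests = [f.coefficients[term] for f in fits]
        vars_ = [f.covariance.loc[term, term] for f in fits]
        df_com = fits[0].n_used - len(fits[0].coefficients)
        pooled = pool_rubin(ests, vars_, df_com=df_com)
        lo, hi = pooled["ci95"]
        rows[term] = {
            "estimate": pooled["estimate"], "within_var": pooled["within_var"],
            "between_var": pooled["between_var"], "total_var": pooled["total_var"],
            "df": pooled["df"], "OR": np.exp(pooled["estimate"]),
            "lower95": np.exp(lo), "upper95": np.exp(hi), "p": pooled["p"],
        }
    return ImputationResult(tables, fits, pd.DataFrame(rows).T)
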