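"""Cohort arm: quartile coding, exposure transformation, nested logistic models.

The exposure (serum cystatin C, mg/L) enters the stroke model either as
quartile indicators (lowest quartile as reference) or as its natural log.
Two nested adjustment sets mirror the usual stepwise confounder strategy:
"model1" adjusts for age group and sex; "model2" further adjusts for
residence, education, marital status, smoking, current drinking, BMI group,
hypertension, diabetes, triglyceride, non-HDL cholesterol and glucose.
Sensitivity variants add hs-CRP or blood-fasting status.

Missing covariate values are handled either as an explicit "missing"
category (categoricals; continuous covariates are mean-imputed with a
missingness indicator) or by complete-case deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import (
    DegenerateQuartileError,
    DomainError,
    EmptyInputError,
    InputError,
    SeparationError,
)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

#: Categorical covariates with their level order; the first level is the
#: dummy-coding reference.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<65", "65-84", ">=85"),
    "sex": ("male", "female"),
    "residence": ("rural", "urban"),
    "education": ("primary", "secondary", "third"),
    "marital": ("married", "others"),
    "smoking": ("never", "former", "current"),
    "drinking": ("no", "yes"),
    "bmi_group": ("<23.9", "24-27.9", ">=28"),
    "hypertension": ("no", "yes"),
    "diabetes": ("no", "yes"),
    "fasting": ("no", "yes"),
}

CONTINUOUS_COVARIATES = ("triglyceride", "non_hdl", "glucose", "hs_crp", "creatinine")

_MODEL1 = ("age_group", "sex")
_MODEL2 = _MODEL1 + (
    "residence", "education", "marital", "smoking", "drinking", "bmi_group",
    "hypertension", "diabetes", "triglyceride", "non_hdl", "glucose",
)

ADJUSTMENTS: dict[str, tuple[str, ...]] = {
    "none": (),
    "model1": _MODEL1,
    "model2": _MODEL2,
    "model2+hscrp": _MODEL2 + ("hs_crp",),
    "model2+fasting": _MODEL2 + ("fasting",),
}

_Z975 = st.norm.ppf(0.975)


def assign_quartiles(values) -> tuple[pd.Series, tuple[float, float, float]]:
    """Quartile labels Q1..Q4 with the 25/50/75 empirical percentiles as cuts.

    Percentiles use linear interpolation between order statistics. Values
    tied with a cutpoint go to the lower quartile, i.e. the intervals are
    (-inf, c25], (c25, c50], (c50, c75], (c75, +inf). Missing values stay
    missing (excluded from analysis downstream).
    """
    values = pd.Series(values, dtype=float)
    obs = values.dropna()
    if obs.empty:
        raise EmptyInputError("no non-missing exposure values")
    if len(obs) < 4:
        raise DomainError("need at least 4 non-missing values to form quartiles")
    cuts = tuple(np.percentile(obs.to_numpy(), [25, 50, 75]))
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise DegenerateQuartileError(f"degenerate quartile cutpoints {cuts}")
    idx = np.searchsorted(cuts, values.to_numpy(), side="left")
    labels = pd.Series(
        np.where(values.isna(), None, np.array(QUARTILE_LABELS)[np.clip(idx, 0, 3)]),
        index=values.index, dtype=object,
    )
    labels[values.isna()] = np.nan
    return labels, cuts


@dataclass
class NormalityReport:
    """One-sample K-S check of raw vs log-transformed values against a
    normal law with matched mean/SD."""
    ks_raw: float
    p_raw: float
    ks_log: float
    p_log: float
    degenerate: bool = False


def log_exposure(values) -> tuple[pd.Series, NormalityReport]:
    """Natural-log transform with a Kolmogorov-Smirnov normality report."""
    values = pd.Series(values, dtype=float)
    obs = values.dropna()
    if (obs <= 0).any():
        raise DomainError("exposure values must be strictly positive for log transform")
    logged = np.log(values)
    lobs = np.log(obs.to_numpy())
    raw = obs.to_numpy()
    if raw.std(ddof=1) == 0 or len(raw) < 3:
        report = NormalityReport(np.nan, np.nan, np.nan, np.nan, degenerate=True)
    else:
        ks_r = st.kstest(raw, "norm", args=(raw.mean(), raw.std(ddof=1)))
        ks_l = st.kstest(lobs, "norm", args=(lobs.mean(), lobs.std(ddof=1)))
        report = NormalityReport(ks_r.statistic, ks_r.pvalue, ks_l.statistic, ks_l.pvalue)
    return logged, report


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit with a Wald OR table.

    ``or_table`` has one row per non-intercept term with columns
    OR, lower95, upper95, p. When the optimiser fails to converge the
    coefficient table is withheld (``or_table is None``).
    """
    coefficients: pd.Series
    covariance: pd.DataFrame
    or_table: pd.DataFrame | None
    n_used: int
    converged: bool
    meta: dict = field(default_factory=dict)


def _or_table(params: pd.Series, cov: pd.DataFrame) -> pd.DataFrame:
    terms = [t for t in params.index if t != "const"]
    se = np.sqrt(np.diag(cov.loc[terms, terms])) if terms else np.array([])
    beta = params.loc[terms].to_numpy()
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    with np.errstate(over="ignore"):   # quasi-separated levels: upper95 = inf
        return pd.DataFrame(
            {
                "OR": np.exp(beta),
                "lower95": np.exp(beta - _Z975 * se),
                "upper95": np.exp(beta + _Z975 * se),
                "p": 2 * st.norm.sf(np.abs(z)),
            },
            index=terms,
        )


def _dummies(series: pd.Series, name: str, levels: Sequence[str],
             missing_policy: str) -> tuple[pd.DataFrame, pd.Series]:
    """Dummy-code one categorical against its reference level.

    Returns the dummy block and a boolean keep-mask (complete-case only).
    """
    s = series.astype(object)
    keep = pd.Series(True, index=s.index)
    if missing_policy == "category":
        s = s.where(s.notna(), "missing")
        use_levels = list(levels[1:]) + (["missing"] if (s == "missing").any() else [])
    else:
        keep = s.notna()
        use_levels = list(levels[1:])
    block = pd.DataFrame(index=s.index)
    for lev in use_levels:
        block[f"{name}[{lev}]"] = (s == lev).astype(float)
    return block, keep


def build_design(table: pd.DataFrame, exposure_spec: str = "quartile",
                 adjustment: str = "model2", missing_policy: str = "category",
                 extra_columns: Mapping[str, pd.Series] | None = None,
                 drop_covariates: Sequence[str] = ()) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Assemble the outcome vector and model matrix for a logistic fit."""
    if adjustment not in ADJUSTMENTS:
        raise InputError(f"unknown adjustment set {adjustment!r}")
    if missing_policy not in ("category", "complete-case"):
        raise InputError(f"unknown missing policy {missing_policy!r}")
    if table["stroke"].isna().any():
        raise InputError("outcome (stroke) must be non-missing in analysed rows")

    df = table.loc[table["cystatin_c"].notna()].copy()
    meta: dict = {"exposure_spec": exposure_spec, "adjustment": adjustment,
                  "missing_policy": missing_policy}
    X = pd.DataFrame(index=df.index)
    keep = pd.Series(True, index=df.index)

    if exposure_spec == "quartile":
        labels, cuts = assign_quartiles(df["cystatin_c"])
        meta["quartile_cutpoints"] = cuts
        for q in QUARTILE_LABELS[1:]:
            X[q] = (labels == q).astype(float)
    elif exposure_spec == "log":
        logged, report = log_exposure(df["cystatin_c"])
        meta["normality"] = report
        X["log_cystatin_c"] = logged
    elif exposure_spec == "none":
        pass
    else:
        raise InputError(f"unknown exposure spec {exposure_spec!r}")

    covariates = [c for c in ADJUSTMENTS[adjustment] if c not in drop_covariates]
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            block, k = _dummies(df[cov], cov, CATEGORICAL_LEVELS[cov], missing_policy)
            X = pd.concat([X, block], axis=1)
            keep &= k
        else:  # continuous
            col = pd.to_numeric(df[cov], errors="coerce")
            if missing_policy == "category":
                if col.isna().any():
                    X[f"{cov}_missing"] = col.isna().astype(float)
                    col = col.fillna(col.mean())
                X[cov] = col
            else:
                keep &= col.notna()
                X[cov] = col

    if extra_columns:
        for name, series in extra_columns.items():
            X[name] = pd.to_numeric(series.reindex(df.index), errors="coerce")
            keep &= X[name].notna()

    y = df["stroke"].astype(float)
    X = X.loc[keep]
    y = y.loc[keep]
    # drop constant (zero-variance) columns, e.g. unobserved dummy levels
    nunique = X.nunique()
    dropped = [c for c in X.columns if nunique[c] <= 1]
    if dropped:
        X = X.drop(columns=dropped)
        meta["dropped_terms"] = dropped
    X = sm.add_constant(X, has_constant="add")
    meta["n_used"] = int(len(y))
    return y, X, meta


def fit_logistic(table: pd.DataFrame, exposure_spec: str = "quartile",
                 adjustment: str = "model2", missing_policy: str = "category",
                 **design_kwargs) -> FitResult:
    """Fit the stroke logistic model and return coefficients with Wald ORs."""
    y, X, meta = build_design(table, exposure_spec, adjustment, missing_policy,
                              **design_kwargs)
    if y.nunique() < 2:
        raise SeparationError("outcome is constant in the analysed rows")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # IRLS with deviance-based convergence (the R glm behaviour):
            # quasi-separated covariate levels get huge SEs, not a failure
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    converged = bool(res.converged)
    params = res.params
    cov = pd.DataFrame(res.cov_params(), index=params.index, columns=params.index)
    table_or = _or_table(params, cov) if converged else None
    return FitResult(params, cov, table_or, int(len(y)), converged, meta)


# ---------------------------------------------------------------------------
# subgroup / interaction analysis
# ---------------------------------------------------------------------------

#: stratifier name -> (derivation, covariate to drop from adjustment)
_STRATIFIERS = ("sex", "age", "obesity", "residence", "smoking",
                "hypertension", "diabetes")


def _stratum_series(table: pd.DataFrame, strata_var: str,
                    age_cut: float = 65.0, include_cut_in_older: bool = True):
    """Binary stratifier series and the adjustment covariate it replaces."""
    if strata_var == "sex":
        return table["sex"], "sex"
    if strata_var == "residence":
        return table["residence"], "residence"
    if strata_var == "hypertension":
        return table["hypertension"], "hypertension"
    if strata_var == "diabetes":
        return table["diabetes"], "diabetes"
    if strata_var == "age":
        if "age" in table.columns:
            age = pd.to_numeric(table["age"], errors="coerce")
            older = age >= age_cut if include_cut_in_older else age > age_cut
            s = pd.Series(np.where(older, ">65", "<65"), index=table.index, dtype=object)
            s[age.isna()] = np.nan
        else:
            s = table["age_group"].map(lambda g: np.nan if pd.isna(g)
                                       else ("<65" if g == "<65" else ">65"))
        return s, "age_group"
    if strata_var == "obesity":
        s = table["bmi_group"].map(lambda g: np.nan if pd.isna(g)
                                   else ("yes" if g == ">=28" else "no"))
        return s, "bmi_group"
    if strata_var == "smoking":
        s = table["smoking"].map(lambda g: np.nan if pd.isna(g)
                                 else ("never" if g == "never" else "current/quit"))
        return s, "smoking"
    raise InputError(f"unknown stratifier {strata_var!r}; choose from {_STRATIFIERS}")


@dataclass
class SubgroupResult:
    strata_var: str
    per_stratum: dict          # level -> FitResult
    interaction_p: dict        # quartile label -> Wald p of the product term
    flagged: list              # strata excluded (zero events or too small)


def subgroup_analysis(table: pd.DataFrame, strata_var: str,
                      adjustment: str = "model2",
                      missing_policy: str = "category",
                      age_cut: float = 65.0,
                      include_cut_in_older: bool = True) -> SubgroupResult:
    """Per-stratum quartile fits plus per-quartile interaction p-values.

    Each stratum refits the requested adjustment set minus the stratifying
    covariate. Interaction p-values come from Wald tests of the
    quartile-by-stratum product terms in a pooled model, one per quartile
    contrast. Strata with zero events are flagged and excluded.
    """
    strat, drop_cov = _stratum_series(table, strata_var, age_cut, include_cut_in_older)
    levels = [lev for lev in pd.unique(strat.dropna())]
    if len(levels) < 2:
        raise InputError(f"stratifier {strata_var!r} has fewer than 2 observed levels")

    per_stratum: dict = {}
    flagged: list = []
    usable: list = []
    for lev in levels:
        sub = table.loc[strat == lev]
        events = sub["stroke"].sum()
        if events == 0 or events == len(sub):
            flagged.append(lev)
            continue
        try:
            per_stratum[lev] = fit_logistic(
                sub, "quartile", adjustment, missing_policy,
                drop_covariates=(drop_cov,))
            usable.append(lev)
        except (SeparationError, DegenerateQuartileError) as exc:
            flagged.append(lev)
    if len(usable) < 2:
        raise InputError(
            f"fewer than 2 usable strata for {strata_var!r} (flagged: {flagged})")

    # pooled interaction model on the usable strata (binary contrast against
    # the first usable level)
    mask = strat.isin(usable)
    pooled = table.loc[mask].copy()
    s_ind = (strat.loc[mask] != usable[0]).astype(float)

    sub_exposed = pooled.loc[pooled["cystatin_c"].notna()]
    labels, _ = assign_quartiles(sub_exposed["cystatin_c"])
    extra = {"stratum_ind": s_ind}
    for q in QUARTILE_LABELS[1:]:
        qi = (labels == q).astype(float).reindex(pooled.index).fillna(0.0)
        extra[f"{q}:stratum"] = qi * s_ind
    fit = fit_logistic(pooled, "quartile", adjustment, missing_policy,
                       extra_columns=extra, drop_covariates=(drop_cov,))
    interaction_p = {}
    for q in QUARTILE_LABELS[1:]:
        term = f"{q}:stratum"
        if fit.or_table is not None and term in fit.or_table.index:
            interaction_p[q] = float(fit.or_table.loc[term, "p"])
        else:
            interaction_p[q] = np.nan
    return SubgroupResult(strata_var, per_stratum, interaction_p, flagged)


# ---------------------------------------------------------------------------
# descriptive table
# ---------------------------------------------------------------------------

def baseline_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) / n (%) descriptive summary by exposure quartile."""
    labels, _ = assign_quartiles(table["cystatin_c"])
    groups = {"Overall": table.index}
    for q in QUARTILE_LABELS:
        groups[q] = labels.index[labels == q]
    rows = {}
    rows["Participants, N"] = {g: str(len(ix)) for g, ix in groups.items()}
    if "age" in table.columns:
        rows["Age, years, mean (SD)"] = {
            g: f"{table.loc[ix, 'age'].mean():.2f} ({table.loc[ix, 'age'].std():.2f})"
            for g, ix in groups.items()}
    for name, levels in CATEGORICAL_LEVELS.items():
        if name not in table.columns or name == "age_group":
            continue
        for lev in levels:
            rows[f"{name}={lev}, n (%)"] = {
                g: (lambda s: f"{int((s == lev).sum())} "
                    f"({100 * (s == lev).mean():.1f})")(table.loc[ix, name].dropna())
                for g, ix in groups.items()}
    for name in CONTINUOUS_COVARIATES:
        if name not in table.columns:
            continue
        rows[f"{name}, mean (SD)"] = {
            g: f"{table.loc[ix, name].mean():.2f} ({table.loc[ix, name].std():.2f})"
            for g, ix in groups.items()}
    return pd.DataFrame(rows).T[list(groups)]
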