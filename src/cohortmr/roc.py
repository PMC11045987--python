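"""Discrimination: AUC by the Mann-Whitney estimator and the DeLong paired test.

The AUC of a score against a binary outcome is the probability that a
randomly chosen case scores above a randomly chosen control, with ties
counted one-half. DeLong's test compares two correlated AUCs measured on
the same participants using the structural-components (placement-value)
estimate of the covariance of the AUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from .errors import DomainError, InputError


def _midrank(x: np.ndarray) -> np.ndarray:
    return st.rankdata(x, method="average")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """AUC plus per-case and per-control placement values (tie-adjusted)."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = len(cases), len(controls)
    tx = _midrank(cases)
    ty = _midrank(controls)
    tz = _midrank(np.concatenate([cases, controls]))
    auc_val = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n                 # one per case
    v01 = 1.0 - (tz[m:] - ty) / m           # one per control
    return float(auc_val), v10, v01


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1} or len(uniq) < 2:
        raise DomainError("labels must contain both classes coded 0/1")
    return scores, labels.astype(int)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: mean over case-control pairs of [case > control] + 1/2 ties."""
    scores, labels = _check(scores, labels)
    value, _, _ = _placements(scores, labels)
    return value


@dataclass
class RocComparison:
    auc_a: float
    auc_b: float
    auc_difference: float
    variance_of_difference: float
    z: float
    p: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> RocComparison:
    """Paired DeLong comparison of two AUCs on identical participants."""
    scores_a, labels_a = _check(scores_a, labels)
    scores_b, labels_b = _check(scores_b, labels)
    if len(scores_a) != len(scores_b):
        raise InputError("paired scores must have equal length")

    auc_a, v10_a, v01_a = _placements(scores_a, labels_a)
    auc_b, v10_b, v01_b = _placements(scores_b, labels_b)
    m, n = len(v10_a), len(v01_a)

    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = (d10.var(ddof=1) / m if m > 1 else 0.0) \
        + (d01.var(ddof=1) / n if n > 1 else 0.0)
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return RocComparison(auc_a, auc_b, 0.0, 0.0, 0.0, 1.0)
        return RocComparison(auc_a, auc_b, diff, 0.0, np.inf * np.sign(diff),
                             np.nan, degenerate=True)
    z = diff / np.sqrt(var)
    p = min(1.0, float(2 * st.norm.sf(abs(z))))
    return RocComparison(auc_a, auc_b, diff, float(var), float(z), p)


def compare_markers(table, marker_a: str = "cystatin_c",
                    marker_b: str = "creatinine",
                    outcome: str = "stroke") -> RocComparison:
    """Crude head-to-head AUC comparison of two biomarkers in a cohort table.

    Rows missing either marker are dropped (scores must be paired).
    """
    sub = table.dropna(subset=[marker_a, marker_b, outcome])
    return delong_test(sub[marker_a].to_numpy(float),
                       sub[marker_b].to_numpy(float),
                       sub[outcome].to_numpy(int))
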