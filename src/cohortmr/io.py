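"""Plain-text interchange formats.

Cohort tables travel as comma-delimited text with a header row and empty
cells for missing values.  GWAS summary statistics travel as tab-delimited
text with the conventional column set (snp, chr, pos, effect_allele,
other_allele, eaf, beta, se, pval, n; positions 1-based).  Pairwise LD is a
tab-delimited triplet file (snp_a, snp_b, r2); absent pairs are read as
r2 = 0.  Truth sidecars (simulation ground truth) are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

SUMSTATS_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_VALID_BASES = frozenset("ACGT")


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sumstats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, columns=SUMSTATS_COLUMNS)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"summary-statistics file {path} lacks columns {missing}")
    validate_sumstats(df)
    return df


def validate_sumstats(df: pd.DataFrame) -> None:
    if (df["se"] <= 0).any():
        raise InputError("summary statistics contain non-positive standard errors")
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].isin(list(_VALID_BASES))
        if bad.any():
            raise InputError(f"invalid base in column {col}: {df.loc[bad, col].unique()!r}")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise InputError("effect and other allele identical for some SNPs")
    if df["snp"].duplicated().any():
        raise InputError("duplicate SNP ids within one study")


class LDReference:
    """Symmetric pairwise r-squared lookup backed by a dict.

    Pairs never recorded are treated as r2 = 0 (unlinked).
    """

    def __init__(self, pairs=None):
        self._r2 = {}
        if pairs is not None:
            for a, b, r2 in pairs:
                self.set(a, b, float(r2))

    @staticmethod
    def _key(a, b):
        return (a, b) if a <= b else (b, a)

    def set(self, a, b, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0) or not np.isfinite(r2):
            raise InputError(f"malformed LD triplet: r2={r2!r} for ({a}, {b})")
        self._r2[self._key(a, b)] = r2

    def r2(self, a, b) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self):
        return len(self._r2)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def write_ld(ld: LDReference, path) -> None:
    ld.to_frame().to_csv(path, sep="\t", index=False)


def read_ld(path) -> LDReference:
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise InputError(f"LD file {path} lacks column {col}")
    return LDReference(zip(df["snp_a"], df["snp_b"], df["r2"]))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=2, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
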