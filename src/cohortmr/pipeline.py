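"""End-to-end orchestration of the cohort and MR arms from one config.

``run_pipeline`` executes the enabled stages in dependency order
(synthesize -> cohort models -> spline -> subgroups -> imputation ->
discrimination; synthesize -> select -> clump -> harmonize -> estimate),
writes table-shaped result files, and records a machine-readable manifest
(inputs, per-stage seeds, file checksums) so identical config+seed reruns
produce identical deterministic-stage checksums.

A single global seed deterministically spawns per-stage substreams keyed by
stage name, so enabling or disabling one stage never reshuffles another
stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mr as mr_mod
from .cohort import (
    QUARTILE_LABELS,
    baseline_table,
    fit_logistic,
    subgroup_analysis,
)
from .errors import CohortMRError, ConfigurationError, PipelineError
from .impute import impute_and_pool
from .io import (
    read_cohort, read_ld, read_sumstats,
    write_cohort, write_ld, write_sumstats, write_truth,
)
from .roc import compare_markers
from .simulate import CohortConfig, GwasSimConfig, generate_cohort, generate_gwas_pair
from .spline import dose_response_curve

log = logging.getLogger("cohortmr")

_STAGE_TAG = 0x636D72  # package-wide salt for per-stage substreams


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed, independent of stage execution order."""
    h = hashlib.sha256(f"{_STAGE_TAG}:{stage}".encode()).digest()
    return (int.from_bytes(h[:4], "big") ^ int(global_seed)) % (2 ** 31)


@dataclass
class RunConfig:
    """Declarative run description (usually loaded from YAML)."""
    seed: int = 0
    outdir: str = "cohortmr_run"
    cohort: dict | None = field(default_factory=dict)
    mr: dict | None = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(seed=int(raw.get("seed", 0)), outdir=raw.get("outdir", "cohortmr_run"),
                   cohort=raw.get("cohort"), mr=raw.get("mr"))

    def validate(self) -> None:
        if not self.cohort and not self.mr:
            raise ConfigurationError("at least one arm (cohort or mr) must be enabled")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_or_table(fit, path: Path, label: str) -> None:
    if fit.or_table is None:
        path.write_text(f"# {label}: fit did not converge\n")
        return
    out = fit.or_table.copy()
    out.insert(0, "term", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _cohort_arm(cfg: dict, seed: int, outdir: Path, manifest: dict) -> None:
    models = cfg.get("models", ["model1", "model2"])
    missing_policy = cfg.get("missing_policy", "category")

    if "data" in cfg:
        table = read_cohort(cfg["data"])
        truth = None
    else:
        sim = dict(cfg.get("sim", {}))
        sim.setdefault("seed", stage_seed(seed, "cohort-sim"))
        cc = CohortConfig(**sim)
        table, truth = generate_cohort(cc)
        write_cohort(table, outdir / "cohort_table.csv")
        write_truth(truth, outdir / "cohort_truth.json")
    manifest["cohort"] = {"n": int(len(table)), "models": models,
                          "missing_policy": missing_policy,
                          "seed": stage_seed(seed, "cohort-sim")}

    baseline_table(table).to_csv(outdir / "table1_baseline.tsv", sep="\t")

    # Table-2-shaped: quartile and log-continuous exposure under each model
    rows = []
    for spec in ("quartile", "log"):
        for model in models:
            fit = fit_logistic(table, spec, model, missing_policy)
            if fit.or_table is None:
                continue
            terms = QUARTILE_LABELS[1:] if spec == "quartile" else ["log_cystatin_c"]
            for t in terms:
                r = fit.or_table.loc[t]
                rows.append((spec, model, t, r["OR"], r["lower95"], r["upper95"],
                             r["p"], fit.n_used, fit.converged))
    pd.DataFrame(rows, columns=["exposure", "model", "term", "OR", "lower95",
                                "upper95", "p", "n_used", "converged"]
                 ).to_csv(outdir / "table2_associations.tsv", sep="\t",
                          index=False, float_format="%.6g")

    # subgroups (Table-3-shaped)
    sub_rows = []
    for var in cfg.get("subgroups", []):
        res = subgroup_analysis(table, var, missing_policy=missing_policy)
        for lev, fit in res.per_stratum.items():
            for q in QUARTILE_LABELS[1:]:
                if fit.or_table is not None and q in fit.or_table.index:
                    r = fit.or_table.loc[q]
                    sub_rows.append((var, lev, q, r["OR"], r["lower95"],
                                     r["upper95"], r["p"], res.interaction_p[q]))
    if sub_rows:
        pd.DataFrame(sub_rows, columns=["stratifier", "stratum", "quartile", "OR",
                                        "lower95", "upper95", "p", "p_interaction"]
                     ).to_csv(outdir / "table3_subgroups.tsv", sep="\t",
                              index=False, float_format="%.6g")

    if cfg.get("spline", True):
        curve = dose_response_curve(table, adjustment=cfg.get("spline_model", "model2"),
                                    missing_policy=missing_policy)
        curve.grid.to_csv(outdir / "spline_curve.tsv", sep="\t", index=False,
                          float_format="%.6g")
        manifest["cohort"]["spline_knots"] = list(curve.knots)
        manifest["cohort"]["spline_warnings"] = curve.warnings

    imp_cfg = cfg.get("imputation", {})
    if imp_cfg.get("enabled", False):
        res = impute_and_pool(table, m=int(imp_cfg.get("m", 5)),
                              seed=stage_seed(seed, "imputation"),
                              sweeps=int(imp_cfg.get("sweeps", 10)))
        out = res.pooled.copy()
        out.insert(0, "term", out.index)
        out.to_csv(outdir / "table2_imputed.tsv", sep="\t", index=False,
                   float_format="%.6g")

    if cfg.get("discrimination", True) and "creatinine" in table.columns:
        cmp = compare_markers(table)
        pd.DataFrame([{
            "auc_cystatin_c": cmp.auc_a, "auc_creatinine": cmp.auc_b,
            "difference": cmp.auc_difference,
            "variance_of_difference": cmp.variance_of_difference,
            "z": cmp.z, "p": cmp.p,
        }]).to_csv(outdir / "auc_comparison.tsv", sep="\t", index=False,
                   float_format="%.6g")


def _mr_arm(cfg: dict, seed: int, outdir: Path, manifest: dict) -> None:
    if "exposure" in cfg:
        exposure = read_sumstats(cfg["exposure"])
        outcome = read_sumstats(cfg["outcome"])
        ld = read_ld(cfg["ld"]) if "ld" in cfg else None
        truth = None
    else:
        sim = dict(cfg.get("sim", {}))
        sim.setdefault("seed", stage_seed(seed, "gwas-sim"))
        gc = GwasSimConfig(**sim)
        exposure, outcome, ld, truth = generate_gwas_pair(gc)
        write_sumstats(exposure, outdir / "exposure_sumstats.tsv")
        write_sumstats(outcome, outdir / "outcome_sumstats.tsv")
        write_ld(ld, outdir / "ld_reference.tsv")
        write_truth(truth, outdir / "gwas_truth.json")

    p_thr = float(cfg.get("p_threshold", 5e-8))
    selected = mr_mod.select_instruments(exposure, p_thr)
    notes = {}
    if ld is not None and len(selected):
        kept = mr_mod.ld_clump(selected, ld, float(cfg.get("clump_r2", 0.001)),
                               float(cfg.get("clump_kb", 10000)))
        selected = selected.loc[selected["snp"].isin(kept)]
    manifest["mr"] = {"n_selected": int(len(selected)), "p_threshold": p_thr}

    h = mr_mod.harmonize(selected, outcome)
    h.audit.to_csv(outdir / "harmonization_audit.tsv", sep="\t", index=False)
    manifest["mr"]["n_harmonized"] = int(len(h))

    methods = cfg.get("methods", ["ivw", "egger", "presso"])
    rows = []
    if "ivw" in methods:
        est = mr_mod.ivw(h)
        lo, hi = est.ci95
        rows.append(("IVW", est.or_, lo, hi, est.p, est.n_snps))
        manifest["mr"]["cochran_q"] = est.extra["Q"]
        manifest["mr"]["cochran_q_p"] = est.extra["Q_p"]
    if "egger" in methods:
        if len(h) >= 3:
            slope, intercept = mr_mod.egger(h)
            lo, hi = slope.ci95
            rows.append(("Egger-slope", slope.or_, lo, hi, slope.p, slope.n_snps))
            manifest["mr"]["egger_intercept"] = intercept
        else:
            notes["egger"] = "skipped: fewer than 3 instruments"
    if "presso" in methods:
        if len(h) >= 4:
            res = mr_mod.mr_presso(h, n_sim=int(cfg.get("presso_nsim", 1000)),
                                   seed=stage_seed(seed, "presso"))
            lo, hi = res.corrected.ci95
            rows.append(("PRESSO-corrected", res.corrected.or_, lo, hi,
                         res.corrected.p, res.corrected.n_snps))
            manifest["mr"]["presso"] = {
                "global_p": res.global_p, "outliers": res.outliers,
                "distortion_p": res.distortion_p,
            }
        else:
            notes["presso"] = "skipped: fewer than 4 instruments"
    if notes:
        manifest["mr"]["skipped"] = notes
    pd.DataFrame(rows, columns=["method", "OR", "lower95", "upper95", "p", "n_snps"]
                 ).to_csv(outdir / "table4_mr_estimates.tsv", sep="\t",
                          index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled arms; returns the run manifest (also written)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    stages = []
    if config.cohort is not None and config.cohort is not False and config.cohort != {}:
        stages.append(("cohort", _cohort_arm, config.cohort))
    if config.mr is not None and config.mr is not False and config.mr != {}:
        stages.append(("mr", _mr_arm, config.mr))
    if not stages:
        raise ConfigurationError("no arm enabled")

    for name, fn, cfg in stages:
        log.info("stage %s starting", name)
        try:
            fn(cfg, config.seed, outdir, manifest)
        except CohortMRError as exc:
            manifest["stages"].append({"stage": name, "status": "failed",
                                       "error": str(exc)})
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                             default=str))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, "status": "ok"})

    checksums = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                 if p.is_file() and p.name != "manifest.json"}
    manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    report = [f"cohortmr run (seed={config.seed})"]
    for st_ in manifest["stages"]:
        report.append(f"  stage {st_['stage']}: {st_['status']}")
    for fname in checksums:
        report.append(f"  wrote {fname}")
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return manifest
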