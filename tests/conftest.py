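import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cohortmr as cm

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_default():
    """One default-condition synthetic cohort (n=6,501) with its truth record."""
    return cm.generate_cohort(cm.CohortConfig(seed=20260926))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with injected MCAR missingness for fast model tests."""
    cfg = cm.CohortConfig(
        n_participants=1500, seed=11,
        missing_rates={"glucose": 0.15, "smoking": 0.10, "hypertension": 0.05},
    )
    return cm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def gwas_default():
    """Default 223-instrument exposure/outcome pair, no pleiotropy."""
    return cm.generate_gwas_pair(cm.GwasSimConfig(seed=77))


@pytest.fixture(scope="session")
def harmonized_default(gwas_default):
    exposure, outcome, ld, truth = gwas_default
    sel = cm.mr.select_instruments(exposure)
    return cm.mr.harmonize(sel, outcome), truth


def make_2x2(n_exposed, cases_exposed, n_unexposed, cases_unexposed):
    """Cohort-shaped table holding a 2x2 layout as a binary exposure proxy.

    Exposure values are two constants so that quartile machinery is not
    involved; callers fit with a hand-built indicator column instead.
    """
    stroke = np.r_[np.ones(cases_exposed), np.zeros(n_exposed - cases_exposed),
                   np.ones(cases_unexposed), np.zeros(n_unexposed - cases_unexposed)]
    exposed = np.r_[np.ones(n_exposed), np.zeros(n_unexposed)]
    return pd.DataFrame({"stroke": stroke.astype(int), "exposed": exposed,
                         "cystatin_c": np.where(exposed == 1, 1.5, 0.7)})
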