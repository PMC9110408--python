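import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from brecansurv import DesignSpec, SimulationConfig, fit_cox, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_cohort_df(n=6, **overrides) -> pd.DataFrame:
    """Small hand-buildable cohort frame with clean defaults."""
    base = {
        "id": [f"p{i}" for i in range(n)],
        "age_dx": [55.0] * n,
        "sex": ["female"] * n,
        "year_dx": [2008] * n,
        "stage": ["I"] * n,
        "her2": ["neg"] * n,
        "er": ["pos"] * n,
        "pr": ["pos"] * n,
        "adherence_rate": [0.9] * n,
        "followup_years": [5.0] * n,
        "dead": [False] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def excess_only_config():
    from dataclasses import replace
    return replace(SimulationConfig(seed=42), lifetable_r0=0.0)


@pytest.fixture(scope="session")
def sim_bundle(default_config):
    """Default-condition cohort with its life table and a C3 fit."""
    cohort = simulate_cohort(default_config)
    table = default_config.make_lifetable()
    fit = fit_cox(cohort, DesignSpec.C3())
    return cohort, table, fit
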