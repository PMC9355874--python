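import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chforge.caller import FilterConfig
from chforge.resources import default_resources
from chforge.simulate import SimulationConfig, simulate_cohort, simulate_variant_calls

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def resources():
    return default_resources()


@pytest.fixture(scope="session")
def filter_cfg():
    return FilterConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort (n=2,000) shared across read-only tests."""
    cfg = SimulationConfig(n_individuals=2_000, seed=11)
    pheno, truth = simulate_cohort(cfg)
    calls = simulate_variant_calls(truth, cfg)
    return cfg, pheno, truth, calls


@pytest.fixture()
def toy_callset():
    """Hand-built callset/phenotype pair for the characterization tests."""
    callset = pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "ch_status": [True, True, True, False],
        "genes": ["DNMT3A", "TET2", "DNMT3A,TET2", ""],
        "max_vaf": [0.15, 0.08, 0.30, float("nan")],
        "clone_class": ["large", "small", "large", None],
    })
    pheno = pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "age": [55, 60, 65, 50],
        "sex": ["female", "male", "female", "male"],
    })
    return callset, pheno
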