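import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famcna import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    """Desk-scale cohort: 100 markers/chromosome, small groups."""
    return sd.SimulationConfig(
        n_markers_per_chromosome=100,
        n_reference_samples=10,
        groups=sd.GroupSizes(chek2_low=6, chek2_high=2, brcax_low=8,
                             brcax_high=2, brca1=4, brca2=2),
        seed=11,
    )


@pytest.fixture(scope="session")
def default_cohort() -> sd.SimulatedCohort:
    """The full default cohort (120 tumours, 90 references), seeded."""
    return sd.simulate_cohort(sd.SimulationConfig(seed=20260118))


@pytest.fixture(scope="session")
def default_expression(default_cohort):
    cfg = sd.SimulationConfig(seed=20260118)
    return sd.simulate_expression(cfg, default_cohort.truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
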