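import numpy as np
import pytest

from epicho import SimulationConfig, generate_promoter
from epicho.simulate import CloneProfile, MARKS


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def annotation(default_config):
    return generate_promoter(default_config)


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """Study layout with all error and noise rates zeroed."""
    return SimulationConfig(
        seed=11,
        conversion_failure_rate=0.0,
        inappropriate_conversion_rate=0.0,
        missing_call_rate=0.0,
        ct_noise_sd=0.0,
        titer_noise_cv=0.0,
    )


def make_clone(name="clone", occupancy=(0.5, 0.5), methylation=0.0,
               hc_lc=50.0, copies=1.0, retention=0.5) -> CloneProfile:
    return CloneProfile(
        name=name,
        occupancy=tuple(occupancy),
        h2a_pct_input=10.0,
        enrichment_rel_h2a={m: 100.0 for m in MARKS},
        faire_pct_input=20.0,
        hc_lc_pct=hc_lc,
        methylation_rate=methylation,
        copy_number=copies,
        titer_retention=retention,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
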