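import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trunkdate as td

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

SEED = td.DEFAULT_SEED


@pytest.fixture(scope="session")
def verburg_sim() -> td.ObservationSet:
    """The default untruncated lognormal simulation (10,600 rows)."""
    return td.simulate_from_dating(td.VERBURG, seed=SEED)


@pytest.fixture(scope="session")
def truncated(verburg_sim) -> td.ObservationSet:
    return td.truncate(verburg_sim, td.TruncationWindow())


@pytest.fixture(scope="session")
def approach1_fit(truncated):
    """(model, fitting set) pair for the restriction-and-extrapolation fit."""
    return td.run_approach1(truncated, seed=SEED + 11, with_data=True)


@pytest.fixture(scope="session")
def approach2_model(truncated):
    return td.run_approach2(truncated, seed=SEED + 23)


@pytest.fixture(scope="session")
def approach3_model(truncated):
    return td.run_approach3(truncated)
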