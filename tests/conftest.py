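import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from arenanav import ArenaConfig, CohortSpec, score_cohort, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture(scope="session")
def small_cohort(arena):
    """10 + 10 participants with encoding paths; reused across tests."""
    spec = CohortSpec(n_per_group=10, seed=42, arena=arena)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def scored(small_cohort, arena):
    return score_cohort(small_cohort, arena)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
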