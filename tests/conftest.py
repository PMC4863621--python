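import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from magverify.simulate import (
    CommunityConfig,
    simulate_community,
    simulate_depth_tracks,
)

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> CommunityConfig:
    """Reduced community for module-level tests (full-size benchmark runs
    live in the acceptance tests)."""
    return CommunityConfig(
        n_genomes=4,
        genome_length_bp=150_000,
        n_misbinned=2,
        n_chimeras=1,
        annotations="none",
        scaffold_median_bp=20_000,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return simulate_community(small_config, seed=1)


@pytest.fixture(scope="session")
def small_tracks(small_community):
    return simulate_depth_tracks(small_community, seed=1)
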