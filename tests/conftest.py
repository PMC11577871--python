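import pytest
from hypothesis import HealthCheck, settings

from panspecies import StudyConfig, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study():
    """A full synthetic study at the default (study-scale) configuration."""
    return generate_study(StudyConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A small, fast study for I/O round-trip and pipeline tests."""
    cfg = StudyConfig(
        cluster_sizes=(8, 4, 5, 6),
        n_core_common=60,
        n_type_core_per_cluster=(5, 6, 7, 8),
        accessory_pool_size=300,
        n_duplicate_pairs=1,
        seed=23,
    )
    return generate_study(cfg)
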