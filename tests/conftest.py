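import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from pkadirect import (  # noqa: E402
    ClusterSpec,
    RunConfig,
    build_species,
    builtin_compounds,
    run_pipeline,
)


@pytest.fixture(scope="session")
def panel():
    return builtin_compounds()


@pytest.fixture(scope="session")
def benzoic(panel):
    return panel[0]


@pytest.fixture(scope="session")
def acid_cluster(benzoic):
    return build_species(ClusterSpec(kind="acid", compound=benzoic))


@pytest.fixture(scope="session")
def base_cluster(benzoic):
    return build_species(ClusterSpec(kind="base", compound=benzoic))


@pytest.fixture(scope="session")
def hydroxide_cluster():
    return build_species(ClusterSpec(kind="hydroxide"))


@pytest.fixture(scope="session")
def water_cluster():
    return build_species(ClusterSpec(kind="water"))


@pytest.fixture(scope="session")
def full_mock_run():
    """One full-panel, all-functional pipeline run on the mock engine."""
    return run_pipeline(RunConfig())
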