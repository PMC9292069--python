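import pytest

from pandemic_cea import AccrualSchedule, PopulationScale, build_bundled_scenarios


@pytest.fixture(scope="session")
def bundled():
    """The six back-solved bundled scenarios, keyed by name."""
    return {sc.key: sc for sc in build_bundled_scenarios()}


@pytest.fixture(scope="session")
def schedule():
    return AccrualSchedule.default()


@pytest.fixture(scope="session")
def million_adults():
    return PopulationScale(n_adults=1_000_000)
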