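import pytest
from hypothesis import settings

from pprh.minigene_fixtures import MinigeneSpec, make_fixture_set

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_set():
    """Default seeded minigene pair shared across tests."""
    return make_fixture_set(MinigeneSpec(seed=42))
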