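import pytest

from caindex import WeightScheme, load_fixture


@pytest.fixture(scope="session")
def study_matrix():
    """The packaged capuchin forearm study matrix (reference Cebus)."""
    return load_fixture()


@pytest.fixture(scope="session")
def default_scheme():
    return WeightScheme()
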