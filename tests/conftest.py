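import pytest

from ferretforge.synth import FixtureSpec, make_taxonomy


@pytest.fixture(scope="session")
def toy_taxonomy():
    """Default two-lineage toy taxonomy and the full 19-name bin set."""
    return make_taxonomy(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def tree(toy_taxonomy):
    return toy_taxonomy[0]


@pytest.fixture(scope="session")
def bins(toy_taxonomy):
    return toy_taxonomy[1]
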