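import pytest

from ckdsim import load_published_tables
from ckdsim.synthetic_data import generate_bundle


@pytest.fixture(scope="session")
def tables():
    return load_published_tables()


@pytest.fixture(scope="session")
def small_aged_bundle():
    return generate_bundle("small_aged", seed=11)


@pytest.fixture(scope="session")
def degenerate_bundle():
    return generate_bundle("degenerate", seed=11)
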