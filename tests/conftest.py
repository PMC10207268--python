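import numpy as np
import pytest

from fraglink import fixtures


@pytest.fixture(scope="session")
def small_library():
    """Deterministic 50-molecule synthetic library with planted segmentations."""
    spec = fixtures.FixtureSpec(n_molecules=50, seed=11)
    return fixtures.make_library(spec)


@pytest.fixture(scope="session")
def small_examples(small_library):
    return [fixtures.planted_example(e) for e in small_library]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
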