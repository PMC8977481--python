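import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def make_dna(rng):
    def _make(n, alphabet="ACGT"):
        return random_dna(rng, n, alphabet)

    return _make
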