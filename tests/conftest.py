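import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture
def random_dna_factory(rng):
    def make(length: int) -> str:
        return random_dna(rng, length)

    return make
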