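import numpy as np
import pytest

from cactascan.simulate import _random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(n: int, seed: int, gc: float = 0.5) -> str:
    return _random_dna(np.random.default_rng(seed), n, gc)


@pytest.fixture
def make_random_dna():
    return random_dna
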