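import numpy as np
import pytest

from mitorecomb.synthetic_data import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_rng(seed):
    return np.random.default_rng(seed)


def random_seq(seed_or_rng, n, gc=0.5):
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return random_dna(rng, n, gc)
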