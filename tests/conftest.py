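import numpy as np
import pytest

from pohsim import Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_population(genotypes, sex, litter=None, generation_index=0):
    """Small-population helper: genotypes as list-of-lists, sex as 'MFMF...'."""
    g = np.asarray(genotypes)
    sexes = np.array(list(sex), dtype=object)
    if litter is None:
        litter = np.arange(g.shape[0])
    return Population(
        genotypes=g,
        sex=sexes,
        litter_id=np.asarray(litter),
        generation_index=generation_index,
    )


@pytest.fixture
def pop_factory():
    return make_population
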