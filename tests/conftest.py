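import numpy as np
import pytest

from polyandrysim import ModelConfig
from polyandrysim.genetics import Population


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def small_config():
    """Tiny genomes for fast construction-heavy tests."""
    return ModelConfig(n_deleterious_loci=50, n_neutral_loci=40)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_population(n, config, rng, female=None, deme=None):
    """Founder-style population with explicit control of sex and deme."""
    from polyandrysim.genetics import founder_genomes

    trait, dele, neutral = founder_genomes(n, config, rng)
    if female is None:
        female = np.arange(n) < n // 2
    if deme is None:
        deme = np.zeros(n, dtype=np.int64)
    deme = np.asarray(deme, dtype=np.int64)
    return Population(
        ids=np.arange(n, dtype=np.int64), female=np.asarray(female, bool),
        trait=trait, deleterious=dele, neutral=neutral,
        deme=deme, natal_deme=deme.copy(),
        dam_id=np.full(n, -1, np.int64), sire_id=np.full(n, -1, np.int64))
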