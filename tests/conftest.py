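import numpy as np
import pytest

from karyo.band_model import Band
from karyo.examples import african_study, basic_registry
from karyo.synthetic_data import evolve, generate_ancestor


@pytest.fixture(scope="session")
def study():
    return african_study()

@pytest.fixture(scope="session")
def registry():
    return basic_registry()

@pytest.fixture(scope="session")
def by_species(study):
    return {k.species: k for k in study}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ref19():
    return tuple(Band(m) for m in range(1, 20))


def random_pair(seed, n_bands=15, k=3, subband_rate=0.0):
    """Ancestor plus k-reversal derivative, sharing one reference order."""
    anc = generate_ancestor(n_bands, subband_rate, seed=seed, code="ancA1")
    log = evolve(anc, k, seed=seed + 1, code="derA1")
    return anc, log.derived, log
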