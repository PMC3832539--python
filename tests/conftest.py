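import numpy as np
import pytest

from ngsdesign.likelihoods import GenotypeLikelihoods


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gl(rng, n_sites, n_individuals):
    """Random but well-conditioned genotype log-likelihoods."""
    logl = np.log(rng.random((n_sites, n_individuals, 3)) + 1e-3)
    return GenotypeLikelihoods(logl=logl, flip=0.01)


@pytest.fixture
def gl_factory():
    return random_gl
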