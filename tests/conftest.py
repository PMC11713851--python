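import numpy as np
import pytest

import eccmap as em


@pytest.fixture(scope="session")
def geometry():
    return em.FieldGeometry()


@pytest.fixture(scope="session")
def movie(geometry):
    return em.make_bar_apertures(geometry)


@pytest.fixture(scope="session")
def movie_tr(movie):
    return em.resample_to_tr(movie, 2.0)


@pytest.fixture(scope="session")
def hrf():
    return em.HRFSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
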