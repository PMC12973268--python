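import numpy as np
import pytest

from xtbu.fixtures import make_ammine_complex, make_lif
from xtbu.params import load_parameters
from xtbu.scf import SCFSettings


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def lif_short():
    return make_lif(1.25)


@pytest.fixture(scope="session")
def hexammine_fe3():
    return make_ammine_complex("Fe", 3, 6, 6, 2.2)


@pytest.fixture()
def diis_settings():
    return SCFSettings(solver="diis")


@pytest.fixture()
def gdm_settings():
    return SCFSettings(solver="gdm", max_iter=800)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_symmetric(rng, n, scale=0.1):
    a = rng.normal(size=(n, n))
    return scale * (a + a.T)
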