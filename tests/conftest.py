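import numpy as np
import pytest

from socddm import DiffusionParams


@pytest.fixture(scope="session")
def plain_params():
    """No across-trial variability: closed forms apply."""
    return DiffusionParams(v=0.2, a=0.12, z_rel=0.5, ter=0.3)


@pytest.fixture(scope="session")
def var_params():
    """Full seven-parameter set with all variability sources active."""
    return DiffusionParams(v=0.25, a=0.1, z_rel=0.5, ter=0.3,
                           eta=0.08, sz=0.02, st=0.1)


def random_valid_params(rng, with_variability=True):
    """One random parameter set inside the valid domain (s fixed at 0.1)."""
    a = rng.uniform(0.06, 0.25)
    z = rng.uniform(0.3, 0.7)
    ter = rng.uniform(0.1, 0.6)
    if with_variability and rng.random() < 0.8:
        eta = rng.uniform(0.0, 0.25)
        sz = rng.uniform(0.0, 0.8) * 2 * min(z, 1 - z) * a * 0.9
        st = rng.uniform(0.0, 1.6) * ter * 0.9
    else:
        eta = sz = st = 0.0
    return DiffusionParams(v=rng.uniform(-1.0, 1.0), a=a, z_rel=z, ter=ter,
                           eta=eta, sz=sz, st=st)
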