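import numpy as np
import pytest

from gogrow.lgca import LatticeConfig, ModelParams
from gogrow.switching import SwitchParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_lattice():
    return LatticeConfig(width=20, height=20, K=8, b=4)


def make_params(kappa, theta, r_b=0.2, r_d=0.01, lattice=None, seed=0):
    return ModelParams(
        r_b=r_b,
        r_d=r_d,
        switch=SwitchParams(kappa, theta),
        lattice=lattice or LatticeConfig(20, 20, 8, 4),
        seed=seed,
    )
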