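import numpy as np
import pytest

from ecdcm.cohort import BASE_A
from ecdcm.model import CouplingModel, HemodynamicParams, NeuronalNoiseSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stable3():
    """A stable 3-node coupling matrix with off-diagonal structure."""
    g = np.random.default_rng(0)
    A = -np.eye(3) * 0.6 + 0.15 * g.standard_normal((3, 3))
    model = CouplingModel(A=A)
    assert model.is_stable()
    return model


@pytest.fixture
def base4():
    """4-node submatrix of the reference coupling (PCC pair, L-dlPFC, mPFC)."""
    idx = [0, 1, 4, 6]
    return BASE_A[np.ix_(idx, idx)]


@pytest.fixture
def hemo():
    return HemodynamicParams()


@pytest.fixture
def white_noise():
    return NeuronalNoiseSpec(amplitude_alpha=2e-3, exponent_beta=0.0,
                             observation_alpha=1e-10)
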