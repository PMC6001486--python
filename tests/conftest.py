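import numpy as np
import pytest

from spindyn import make_spin_system


@pytest.fixture(scope="session")
def s1():
    return make_spin_system(1)


@pytest.fixture(scope="session")
def s2():
    return make_spin_system(2)


@pytest.fixture(scope="session")
def s3():
    return make_spin_system(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_operator(system, rng, hermitian=False):
    """A dense random operator for property tests."""
    from spindyn import SpinOperator

    n = system.dimension
    M = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    if hermitian:
        M = (M + M.conj().T) / 2
    return SpinOperator(system, M)
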