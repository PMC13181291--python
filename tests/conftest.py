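import numpy as np
import pytest

from sctkit.phantom import PhantomSpec, make_paired_sample


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom grid used across tests (32x32x8 @ 3 mm)."""
    return PhantomSpec(shape=(8, 32, 32))


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def paired_sample(default_spec):
    """One full paired sample on the default 64x64x16 grid (with dose)."""
    return make_paired_sample(default_spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
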