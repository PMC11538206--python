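import numpy as np
import pytest

from petleskit import PhantomSpec, generate_scan


@pytest.fixture(scope="session")
def small_scan():
    """A small phantom scan shared by read-only tests."""
    spec = PhantomSpec(shape=(48, 48, 96), n_lesions=8, seed=11)
    return generate_scan(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
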