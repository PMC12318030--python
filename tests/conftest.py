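import numpy as np
import pytest

from lungct import phantom


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def nodule_phantom(default_spec):
    """One seeded phantom guaranteed to contain a nodule."""
    return phantom.generate_phantom(default_spec, seed=42, with_nodules=True)


@pytest.fixture(scope="session")
def clean_spec():
    return phantom.PhantomSpec(noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
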