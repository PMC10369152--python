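import numpy as np
import pytest

from fdopa import PhantomSpec, build_phantom
from fdopa.validation import desk_schedule


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry 32-frame phantom without noise or motion."""
    return build_phantom(PhantomSpec(seed=11, noise_sigma0=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-geometry 32-frame phantom at the default noise level."""
    return build_phantom(PhantomSpec(seed=21, noise_sigma0=0.5))


@pytest.fixture(scope="session")
def small_noisy_phantom():
    """Desk-schedule small-grid phantom for realignment tests."""
    return build_phantom(PhantomSpec(seed=33, shape=(24, 24, 18),
                                     schedule=desk_schedule(),
                                     noise_sigma0=0.5))


@pytest.fixture(scope="session")
def std_noisy_phantom():
    """Desk-schedule phantom at the default grid size (better rotation
    conditioning for realignment accuracy checks)."""
    return build_phantom(PhantomSpec(seed=37, schedule=desk_schedule(),
                                     noise_sigma0=0.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
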