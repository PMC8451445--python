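import numpy as np
import pytest

from browsevuln.simulate import SimConfig, fixture_small, simulate


@pytest.fixture(scope="session")
def small():
    """Miniature synthetic study: 4 sites, 12 species, 8 fecal samples."""
    return fixture_small(seed=7)


@pytest.fixture(scope="session")
def study():
    """One full-size synthetic study at default effect sizes."""
    return simulate(SimConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
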