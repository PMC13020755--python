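import numpy as np
import pytest

from tfmkit import ElasticSubstrate
from tfmkit.synthetic import render_bead_image


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def substrate():
    return ElasticSubstrate(E=20_000.0, nu=0.5)


@pytest.fixture(scope="session")
def bead_image():
    """A deterministic 192x192 bead image at the standard pixel size."""
    return render_bead_image((192, 192), 0.108, rng=7)
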