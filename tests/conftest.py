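import numpy as np
import pytest

from oligomp import NoiseModel
from oligomp.reference import default_equilibrium_params, default_inhibitors


@pytest.fixture(scope="session")
def params():
    """Reference equilibrium parameters of the GNE system."""
    return default_equilibrium_params()


@pytest.fixture(scope="session")
def inhibitors():
    """Inhibitor models calibrated to the measured IC50s."""
    return default_inhibitors()


@pytest.fixture
def clean_noise():
    """Noise-free measurement: exact species masses, no background."""
    return NoiseModel(peak_cv=0.0, background_rate=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
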