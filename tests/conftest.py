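import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nircal import SpectraSet

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spectra(rng):
    """5 spectra on a 12-point descending grid."""
    wn = np.linspace(10000, 4000, 12)
    absorb = rng.normal(1.0, 0.3, (5, 12))
    ids = [f"S{i}" for i in range(5)]
    return SpectraSet(wn, absorb, ids)
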