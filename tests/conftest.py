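import numpy as np
import pytest
from scipy.stats import norm

from noxithresh import ObserverSpec

#: sqrt(2) * Phi^-1(0.5**(1/3)): signal-to-noise ratio at the 3-down/1-up
#: convergence point, used to place theoretical thresholds exactly.
SNR_AT_CONVERGENCE = float(np.sqrt(2.0) * norm.ppf(0.5 ** (1 / 3)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_observer():
    """Linear transducer, no saturation within the stimulus range."""
    return ObserverSpec(gain=1.0, exponent=1.0, offset=35.0, noise=2.0, lapse=0.0)


@pytest.fixture
def convex_observer():
    """Convex transducer over the noxious range (offset 42 C)."""
    return ObserverSpec(gain=1.0, exponent=2.0, offset=42.0, noise=10.0, lapse=0.0)


@pytest.fixture
def sharp_observer():
    """Near-deterministic observer: tiny noise, always correct for any change."""
    return ObserverSpec(gain=1.0, exponent=1.0, offset=35.0, noise=1e-9, lapse=0.0)


@pytest.fixture
def guessing_observer():
    """Effectively signal-blind observer (near-zero gain)."""
    return ObserverSpec(gain=1e-9, exponent=1.0, offset=35.0, noise=1.0, lapse=0.0)


def observer_with_threshold(threshold: float, direction: str = "decrease") -> ObserverSpec:
    """Linear observer whose theoretical detection threshold is exactly
    ``threshold`` (no saturation: offset 35 C)."""
    return ObserverSpec(
        gain=1.0,
        exponent=1.0,
        offset=35.0,
        noise=threshold / SNR_AT_CONVERGENCE,
        lapse=0.0,
    )
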