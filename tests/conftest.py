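import numpy as np
import pytest

from ffrpipe.spectral import stimulus_peak_frequencies
from ffrpipe.synthetic import StimulusSpec, synthesize_stimulus


@pytest.fixture(scope="session")
def default_spec() -> StimulusSpec:
    return StimulusSpec()


@pytest.fixture(scope="session")
def fast_spec() -> StimulusSpec:
    """Same frequency plan at a reduced sampling rate (speed)."""
    return StimulusSpec(sampling_rate_hz=6000.0)


@pytest.fixture(scope="session")
def default_stimulus(default_spec) -> np.ndarray:
    return synthesize_stimulus(default_spec)


@pytest.fixture(scope="session")
def fast_stimulus(fast_spec) -> np.ndarray:
    return synthesize_stimulus(fast_spec)


@pytest.fixture(scope="session")
def default_peaks(default_stimulus, default_spec) -> dict:
    return stimulus_peak_frequencies(default_stimulus, default_spec)


@pytest.fixture(scope="session")
def fast_peaks(fast_stimulus, fast_spec) -> dict:
    return stimulus_peak_frequencies(fast_stimulus, fast_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
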