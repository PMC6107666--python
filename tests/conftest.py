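import numpy as np
import pytest

from causaldecomp import EEMDParams, TimeSeries, coupled_logistic


@pytest.fixture(scope="session")
def two_tone():
    """Well-separated two-tone signal (periods 8 and 64), 512 samples."""
    t = np.arange(512.0)
    return TimeSeries(np.sin(2 * np.pi * t / 8) + np.sin(2 * np.pi * t / 64),
                      "two_tone")


@pytest.fixture(scope="session")
def fast_params():
    """Small-ensemble EEMD settings for cheap pipeline tests."""
    return EEMDParams(noise_level=0.15, ensemble_size=50)


@pytest.fixture(scope="session")
def logistic_pair():
    return coupled_logistic(400)
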