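import numpy as np
import pytest

from frobs.bands import PAPER_BANDS, build_filter_bank

FS = 2048.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture(scope="session")
def bank(fs):
    """Canonical eight-band Gabor filter bank at the study sampling rate."""
    return build_filter_bank(PAPER_BANDS, fs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
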