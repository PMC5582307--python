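import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from dopbeat import RunConfig, simulate


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    """Reduced-ensemble config: EEMD averaging converges ~1/sqrt(E), so a
    small ensemble is adequate for the synthetic fixtures here."""
    return RunConfig(ensemble_size=10, seed=7)


@pytest.fixture(scope="session")
def record_10db():
    """A standard 1-min synthetic record: 150 beats, mean 400 ms,
    SDNN 13.5 ms, RMSSD 9.5 ms, 10 dB burst SNR."""
    return simulate.make_record(seed=1)


@pytest.fixture(scope="session")
def record_short():
    """A ~25 s record for pipeline tests that do not need a full minute."""
    return simulate.make_record(seed=3, n_beats=60)


@pytest.fixture(scope="session")
def two_tone():
    """50 Hz + 2 Hz two-component signal with its parts, 2 s at 1 kHz."""
    t = np.arange(2000) / 1000.0
    hi = np.sin(2 * np.pi * 50.0 * t)
    lo = np.sin(2 * np.pi * 2.0 * t)
    return hi + lo, hi, lo
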