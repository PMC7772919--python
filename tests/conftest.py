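import numpy as np
import pytest

from ecgdetrend import LevelRange, generate_synthetic_ecg, minmax_normalize

FS = 250.0
DURATION_S = 14.0
N = 3500


@pytest.fixture(scope="session")
def ecg_norm():
    """One normalized 14-s synthetic excerpt (the benchmark's unit input)."""
    sig = minmax_normalize(generate_synthetic_ecg(DURATION_S, FS, 60.0, 0.05, seed=0))
    return sig.with_samples(sig.samples, "synthetic-0")


@pytest.fixture(scope="session")
def lv17():
    return LevelRange(1, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
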