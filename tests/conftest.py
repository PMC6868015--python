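import numpy as np
import pytest

from meanet.io import PipelineConfig
from meanet.simulate import WaveformModel, preset, simulate_trains

FS = 12500.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def hpsc_truth_60s():
    """One hPSC-like well, 60 s, fixed seed — shared across detection tests."""
    p = preset("hPSC_peak")
    p.duration_s = 60.0
    return simulate_trains(p, seed=2)


@pytest.fixture(scope="session")
def hpsc_raw_60s(hpsc_truth_60s):
    from meanet.simulate import synthesize_raw

    return synthesize_raw(hpsc_truth_60s, WaveformModel(), fs=FS)


def greedy_match_count(a, b, tol=1e-3):
    """Shared helper: one-to-one in-order coincidence count."""
    i = j = m = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            m += 1
            i += 1
            j += 1
        elif b[j] < a[i] - tol:
            j += 1
        else:
            i += 1
    return m
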