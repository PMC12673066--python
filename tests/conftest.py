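import numpy as np
import pandas as pd
import pytest

from moltclock import synthetic_data as sd
from moltclock.rhythm_fit import SampleTiming


@pytest.fixture(scope="session")
def dense_timing():
    """36 samples at 0..350 in 10-degree steps (one full cycle)."""
    phi = np.arange(0.0, 360.0, 10.0)
    return SampleTiming(samples=[f"s{i}" for i in range(36)], unwrapped=phi)


@pytest.fixture(scope="session")
def truth_small():
    return sd.make_tf_system(5, 300, cobind_blocks=8, seed=7)


@pytest.fixture(scope="session")
def world_small(truth_small):
    return sd.make_timecourse(truth_small, seed=7)


@pytest.fixture(scope="session")
def truth9():
    """Study-scale system: 9 TFs, 2000 peaks, noise_sd 0.1."""
    return sd.make_tf_system(9, 2000, cobind_blocks=20, seed=11)


@pytest.fixture(scope="session")
def world9(truth9):
    return sd.make_timecourse(truth9, seed=11)


@pytest.fixture(scope="session")
def noiseless_world():
    truth = sd.make_tf_system(5, 400, cobind_blocks=10, seed=5, noise_sd=0.0)
    return sd.make_timecourse(truth, seed=5)


@pytest.fixture(scope="session")
def sc_ring_data():
    rng = np.random.default_rng(21)
    phases = pd.Series(
        rng.uniform(0, 360, 200), index=[f"g{i:04d}" for i in range(200)]
    )
    counts, angles = sd.make_sc_ring(1000, phases, depth=2000, seed=21, amp=0.6)
    return counts, angles, phases
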