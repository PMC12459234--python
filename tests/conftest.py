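import numpy as np
import pytest

from wakemap import TrialConfig, make_layout, simulate_trial
from wakemap.fixtures import fixture


@pytest.fixture(scope="session")
def layout64():
    return make_layout(64, seed=101)


@pytest.fixture(scope="session")
def layout24():
    return make_layout(24, seed=101)


@pytest.fixture(scope="session")
def nrem_trial(layout64):
    """One standard NREM awakening trial (delta -1 s, alpha 0 s, beta +6 s)."""
    cfg = TrialConfig(transient_latency={"delta": -1.0, "alpha": 0.0, "beta": 6.0})
    return simulate_trial(layout64, cfg, seed=3)


@pytest.fixture(scope="session")
def nrem74():
    return fixture("nrem_spontaneous_74", seed=1)


@pytest.fixture(scope="session")
def rem37():
    return fixture("rem_spontaneous_37", seed=1)


def sinusoid_trial(layout, freq, amp=10.0, fs=500):
    """A trial whose scalp channels carry a pure sinusoid (per-channel
    random phase so average referencing leaves it intact)."""
    from wakemap.simulate import N_SAMPLES, T0_INDEX, Trial

    rng = np.random.default_rng(0)
    t = np.arange(N_SAMPLES) / fs
    phases = rng.uniform(0, 2 * np.pi, len(layout.channel_id))
    data = amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    return Trial(data=data.astype(np.float32), fs=fs, t0_index=T0_INDEX,
                 condition="spontaneous_awakening", stage="N2",
                 subject_id="S01", trial_id="sin", time_of_night=3.0,
                 layout=layout)
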