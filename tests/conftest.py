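import numpy as np
import pytest

from teneeg import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """3 channels, 4 ragged trials of random noise at 256 Hz."""
    labels = ["Fz", "Cz", "Pz"]
    trials = [rng.standard_normal((3, t)) for t in (256, 300, 256, 412)]
    return EpochSet("s01", trials, labels, 256.0)


def sinusoid_epochs(
    freq_hz,
    n_channels=2,
    t_samples=256,
    rate=256.0,
    amplitude=1.0,
    phases=None,
    n_trials=1,
):
    """Deterministic sinusoid trials: channel m gets phase phases[m]."""
    if phases is None:
        phases = np.zeros(n_channels)
    t = np.arange(t_samples) / rate
    x = np.stack(
        [amplitude * np.cos(2 * np.pi * freq_hz * t + p) for p in phases]
    )
    labels = [f"C{m + 1}" for m in range(n_channels)]
    return EpochSet("sine", [x.copy() for _ in range(n_trials)], labels, rate)
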