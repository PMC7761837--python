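import numpy as np
import pytest

import synsiggan as sg


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def ecg_spec():
    """A realistic seeded ECG fixture spec: 10 beats at 360 Hz, 10 dB SNR."""
    return sg.FixtureSpec(sg.SignalType.ECG, n_segments=10,
                          segment_length_range=(324, 396), fs=360.0,
                          noise_snr_db=10.0, seed=7)


@pytest.fixture
def sinusoid_segments():
    """64 near-identical one-period sinusoid segments of length 64."""
    gen = np.random.default_rng(123)
    t = np.arange(64) / 64
    return np.array([np.sin(2 * np.pi * t) + 0.05 * gen.standard_normal(64)
                     for _ in range(64)])


@pytest.fixture
def tiny_gan_config():
    return sg.GanConfig(segment_length=32, hidden_size=4, noise_dim=3,
                        n_layers=2, conv_filters=(2, 3), kernel_sizes=(5, 3),
                        stride=3, pool_sizes=(2, 1), batch_size=8, epochs=1,
                        seed=0)
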