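import numpy as np
import pytest

from emgdecomp.simulate import generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free 3-MU record with well-separated templates."""
    return generate_recording(
        n_mus=3, duration_s=3.0, snr_db=None, seed=7, min_feature_distance=0.3
    )


@pytest.fixture(scope="session")
def noisy_recording():
    """Benchmark-style 6-MU record at 20 dB SNR."""
    return generate_recording(n_mus=6, snr_db=20.0, seed=1, min_feature_distance=0.3)
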