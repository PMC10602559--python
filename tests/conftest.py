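import numpy as np
import pytest

from zfheart.simdata import SynthHeartSpec, simulate_heart_video


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless, jitter-free beating heart: 120 bpm, 2 s at 50 fps."""
    return SynthHeartSpec(hr_bpm=120.0, fps=50.0, n_frames=100,
                          ed_semi_axes=(20.0, 10.0),
                          contraction_frac=(0.25, 0.25),
                          noise_sd=0.0, blur_sigma=0.0, jitter_px=0.0)


@pytest.fixture(scope="session")
def clean_video(clean_spec):
    return simulate_heart_video(clean_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
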