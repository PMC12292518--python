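import numpy as np
import pytest

from spinetrack import KinematicsConfig, make_recording


SMALL_KIN = dict(
    n_frames=10,
    total_rom_deg=20.0,
    segment_amplitudes_deg={"C4-C5": 3.0, "C5-C6": 3.0, "C6-C7": 3.0},
    segment_peak_order=("C6-C7", "C5-C6", "C4-C5"),
    image_size=(192, 160),
    vertebra_height_px=15.0,
    spacing_px=19.0,
    noise_sd=0.02,
    occlusion_strength=0.3,
)


@pytest.fixture(scope="session")
def small_recording():
    """A small, fast synthetic recording shared by read-only tests."""
    cfg = KinematicsConfig(seed=7, **SMALL_KIN)
    rec, ann = make_recording(cfg)
    return cfg, rec, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
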