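import numpy as np
import pytest

from sephkit import synth


@pytest.fixture
def one_ring_truth() -> synth.TimeLapseTruth:
    """A single noiseless ring with a full rise/fall lifecycle."""
    ring = synth.RingTruth(
        position=10.0, t_assemble=0.0, t_peak=100.0, t_disassemble=240.0,
        peak_amplitude=400.0, sigma=0.15,
    )
    return synth.TimeLapseTruth(
        rings=(ring,), background_level=50.0, noise_sd=0.0,
        frame_interval=10.0, pixel_size=0.1, n_frames=24, n_positions=200,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)
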