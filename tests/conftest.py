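import numpy as np
import pytest

from triplanar.io_volumes import Block, BlockSchedule, Volume4D
from triplanar.synthetic_data import SynthConfig, generate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def motor_schedule():
    """The canonical 13-block layout: 3 fixation + 10 movement (2 per class)."""
    labels = ["FIXATION", "LH", "RH", "LF", "RF", "FIXATION", "T", "LH", "RH",
              "FIXATION", "LF", "RF", "T"]
    blocks = [Block(5 * i, 5, lab) for i, lab in enumerate(labels)]
    return BlockSchedule(blocks=blocks, n_frames_total=65)


@pytest.fixture
def small_volume(rng, motor_schedule):
    """A 6x7x5x65 volume with strictly positive values, paired frame count."""
    data = 100.0 + rng.random((6, 7, 5, 65))
    return Volume4D(data=data, subject_id="sub-000")


@pytest.fixture
def tiny_synth_cfg():
    """Desk-scale generator config used by fast end-to-end tests."""
    return SynthConfig(dims=(12, 14, 12), frames_per_block=6, roi_radius=2.0, seed=11)


@pytest.fixture
def tiny_samples(tiny_synth_cfg):
    return generate_samples(tiny_synth_cfg, 6)
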