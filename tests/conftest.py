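import numpy as np
import pytest

from rfmotion.config import GridSpec, StimulusConfig
from rfmotion.encode import build_sdh
from rfmotion.pipeline import simulate_session
from rfmotion.stimulus import generate_bmdots


@pytest.fixture
def default_config():
    return StimulusConfig()


@pytest.fixture
def small_config():
    """A reduced field keeping the standard dot density (0.25 per deg^2)."""
    return StimulusConfig(field_width_deg=16, field_height_deg=12, n_dots=48,
                          n_trials=4)


@pytest.fixture
def small_grid():
    return GridSpec.centered(16, 12)


@pytest.fixture
def small_sdh(small_config, small_grid):
    traj = generate_bmdots(small_config, seed=11)
    return build_sdh(traj, small_grid)


@pytest.fixture
def small_session(small_config, small_grid):
    """A short homogeneous-RF synthetic recording (sdh, spikes, ground truth)."""
    cfg = small_config.with_(n_trials=20)
    return simulate_session("homogeneous", cfg, small_grid, seed=7,
                            peak_gain=60.0), cfg
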