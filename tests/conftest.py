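import numpy as np
import pytest
from hypothesis import settings

from stcnc import stimulus, synth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg16() -> stimulus.StimulusConfig:
    return stimulus.StimulusConfig(grid_rows=16, grid_cols=16, seed=11)


@pytest.fixture(scope="session")
def movie16(cfg16) -> stimulus.FrameSequence:
    """A shared white-noise recording long enough for ~5000 spikes per cell
    at the default firing rate."""
    return stimulus.generate_white_noise(cfg16, 36000)


@pytest.fixture(scope="session")
def movie16_short(cfg16) -> stimulus.FrameSequence:
    return stimulus.FrameSequence(config=cfg16, frames=np.array(
        stimulus.generate_white_noise(cfg16, 4000).frames))


@pytest.fixture(scope="session")
def on_cell(cfg16) -> synth.SyntheticCell:
    return synth.make_cell("ON", cfg16, center_um=(850, 850),
                           spatial_sigma_um=70, cell_id="on_ref")


@pytest.fixture(scope="session")
def onoff_cell(cfg16) -> synth.SyntheticCell:
    return synth.make_cell("ON_OFF", cfg16, center_um=(850, 850),
                           spatial_sigma_um=70, cell_id="onoff_ref")
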