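import numpy as np
import pytest

from ecpkit.signal_model import Channel, ContinuousRecording
from ecpkit.synthetic_ephys import NoiseSpec, UnitSpec, generate_recording


@pytest.fixture
def two_channel_recording() -> ContinuousRecording:
    """Small deterministic 2-channel recording for I/O and slicing tests."""
    rng = np.random.default_rng(42)
    data = rng.standard_normal((2, 30000)) * 20.0
    return ContinuousRecording(30000.0, data,
                               [Channel("c34", "CN"), Channel("p23", "putamen")])


@pytest.fixture(scope="session")
def tan_recording_60s():
    """60 s, one tonic 5 Hz unit at SNR 8 over white noise; with ground truth."""
    rec, truth = generate_recording(
        [UnitSpec(cell_class="TAN", mean_rate=5.0, firing_model="poisson")],
        NoiseSpec(), duration=60.0, seed=11)
    return rec, truth
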