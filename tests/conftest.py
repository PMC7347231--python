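import numpy as np
import pytest

from usvsex import segment as sg
from usvsex import synth as sy


@pytest.fixture(scope="session")
def seg_cfg():
    return sg.SegmentationConfig()


@pytest.fixture(scope="session")
def flat_call_spec():
    """50 ms constant-frequency call at 60 kHz."""
    return sy.TrajectorySpec(
        duration_ms=50.0,
        segments=(sy.TrajectorySegment("flat", 60.0, 60.0),))


@pytest.fixture(scope="session")
def sweep_call_spec():
    """60 ms linear up-sweep 50 -> 80 kHz (0.5 kHz/ms)."""
    return sy.TrajectorySpec(
        duration_ms=60.0,
        segments=(sy.TrajectorySegment("up", 50.0, 80.0),))


@pytest.fixture(scope="session")
def flat_call_patch(flat_call_spec, seg_cfg):
    """Noiseless full-band spectrogram patch (233 x T) of the flat call."""
    wave = sy.synthesize_call(flat_call_spec)
    spec = sg.stft_magnitude(wave, seg_cfg)
    return spec
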