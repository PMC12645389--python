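import numpy as np
import pytest

from docndf import GroupParams, RawRecording


ZERO_BANDS = {b: 0.0 for b in ("Delta", "Theta", "Alpha", "Beta", "Gamma")}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def silent_params():
    """Group parameters producing exactly zero background and no bursts."""
    return GroupParams(group_label="MCS", synchrony=0.0, transient_prob=0.0,
                       noise_sd_uV=0.0, band_powers=dict(ZERO_BANDS))


@pytest.fixture
def task_recording(rng):
    """A small task recording with alternating events, for epoch tests."""
    fs = 500.0
    n = 30
    soa = 500
    data = rng.normal(0.0, 5.0, size=(4, n * soa + 1000))
    events = [(500 + i * soa, "DEV" if i % 5 == 4 else "STD")
              for i in range(n)]
    return RawRecording(data=data, fs=fs, labels=["FZ", "CZ", "C3", "PZ"],
                        events=events, state="task")
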