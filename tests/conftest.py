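import numpy as np
import pytest

from sleepphys import synth
from sleepphys.config import SimConfig


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def short_session(cfg):
    """A 10-min synthetic session shared across tests (hypnogram + EEG/EMG)."""
    hyp = synth.gen_hypnogram(cfg, 300)
    rec = synth.gen_eeg_emg(hyp, cfg)
    return hyp, rec
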