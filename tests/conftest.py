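import numpy as np
import pytest

from nvcouple import megforward as mf
from nvcouple import synthdata as sd


@pytest.fixture
def head():
    return mf.HeadModel()


@pytest.fixture
def array():
    return mf.hemisphere_array()


@pytest.fixture
def grid(head):
    return mf.build_grid(head)


@pytest.fixture
def control_truth():
    """One deterministic control subject."""
    return sd.sample_subject("control", "ctl00", np.random.default_rng(42))


@pytest.fixture
def quiet_truth(control_truth):
    """Control subject with all stochastic components switched off."""
    t = control_truth
    t.noise = sd.default_noise()
    for key in ("meg_sensor_sd", "meg_source_broadband", "asl_sd",
                "multiti_sd_frac"):
        t.noise[key] = 0.0
    t.evoked_amp = 0.0
    return t
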