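import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def volume():
    from mitoquant.fcs_kinetics import ObservationVolume

    return ObservationVolume(beam_waist_w=0.2, structural_parameter_s=5.0)


@pytest.fixture
def lags():
    return np.geomspace(1e-5, 1.0, 48)
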