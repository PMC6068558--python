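import numpy as np
import pytest

from radarvitals import PhysioParams, RadarConfig, baseband_iq


@pytest.fixture
def cfg():
    """Default acquisition: 60 GHz (5 mm), 100 Hz, 10 s."""
    return RadarConfig()


@pytest.fixture
def ambiguity_params():
    """The canonical hard case: heartbeat on the 4th respiration harmonic."""
    return PhysioParams(
        mr=1.0, mh=0.08, fr=0.3, fh=1.2, phi_r=1.1, phi_h=2.3, psi=0.7
    )


@pytest.fixture
def ambiguity_signal(ambiguity_params, cfg):
    return baseband_iq(ambiguity_params, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
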