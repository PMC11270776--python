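import numpy as np
import pytest

from aortaflow import profiles, synthetic

RADIUS = 0.01  # m, abdominal aorta


@pytest.fixture(scope="session")
def generic_pulse():
    return profiles.generic_flow_pulse()


@pytest.fixture
def truth_factory(generic_pulse):
    def make(kind="womersley", seed=0, noise=0.0, radius=RADIUS):
        return synthetic.TruthRecord(flow_pulse=generic_pulse, radius=radius,
                                     profile_kind=kind, seed=seed,
                                     noise_level=noise)
    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
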