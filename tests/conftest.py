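import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import petparam as pp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule():
    return pp.FrameSchedule.default()


@pytest.fixture(scope="session")
def inp(schedule):
    return pp.make_input_function(schedule=schedule)


@pytest.fixture(scope="session")
def weights(schedule):
    return pp.frame_weights(schedule)


@pytest.fixture(scope="session")
def ref_truth():
    # well-conditioned reference: VT' = 5, k2' = 0.06, no blood signal
    return pp.GroundTruth(K1=0.3, k2=0.06, VB=0.0)


@pytest.fixture(scope="session")
def ref_tac(ref_truth, inp, schedule):
    return pp.make_tissue_tac(ref_truth, inp, schedule)


@pytest.fixture(scope="session")
def target_truth():
    # DVR = 4, BPND = 3, R1 = 1.2, k2a = 0.018 (inside the default basis grid)
    return pp.GroundTruth(K1=0.36, k2=0.018, VB=0.0)


@pytest.fixture(scope="session")
def target_tac(target_truth, inp, schedule):
    return pp.make_tissue_tac(target_truth, inp, schedule)
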