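import numpy as np
import pytest

from fvcea import (
    RewardSchedule,
    build_transition_model,
    load_parameter_table,
    propagate,
)


@pytest.fixture(scope="session")
def params():
    return load_parameter_table()


@pytest.fixture(scope="session")
def std_model(params):
    return build_transition_model(params, "standard")


@pytest.fixture(scope="session")
def fv_model(params):
    return build_transition_model(params, "fv")


@pytest.fixture(scope="session")
def std_traj(std_model):
    return propagate(std_model, 8)


@pytest.fixture(scope="session")
def fv_traj(fv_model):
    return propagate(fv_model, 8)


@pytest.fixture(scope="session")
def schedule(params):
    return RewardSchedule.from_parameters(params)


# End-of-horizon occupancies from an independent brute-force propagation
# of the published baseline matrices (hand-assembled, cycle-by-cycle).
STD_END_OCCUPANCY = np.array([0.56572439, 0.15804052, 0.27623509])
FV_END_OCCUPANCY = np.array([0.60707082, 0.13092815, 0.26200103])
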