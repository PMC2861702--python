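import numpy as np
import pytest

import fbnoise as fb
from fbnoise.models import ModelSpec


@pytest.fixture(scope="session")
def sp_model():
    return fb.build_model("single_positive")


@pytest.fixture(scope="session")
def sp_steady(sp_model):
    return fb.compute_steady_states(sp_model, 0.0, 1.0)


@pytest.fixture(scope="session")
def linear_filter():
    """First-order low-pass filter dy/dt = (u - y)/tau as a plugin model."""
    tau_f = 2.0

    def rhs(t, y, s):
        return np.stack([(s - y[..., 0]) / tau_f], axis=-1)

    return ModelSpec(
        model_id="user_plugin",
        state_names=("y",),
        output_index=0,
        params={"tau_f": tau_f},
        rhs=rhs,
        box_lo=np.array([-np.inf]),
        box_hi=np.array([np.inf]),
        jacobian=lambda y, s: np.array([[-1.0 / tau_f]]),
        stimulus_jac=lambda y, s: np.array([1.0 / tau_f]),
    )
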