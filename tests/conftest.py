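import numpy as np
import pytest

from gonogo import MODELS, ParameterVector, TaskConfig, make_session, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def m7_params():
    return ParameterVector.from_constrained(
        MODELS["M7"],
        rho=4.0, eps=0.3, go_bias=0.8, pi=1.0, kappa=0.5, phi_int=0.3, phi_diff=0.4,
    )


@pytest.fixture
def m7_dataset(m7_params):
    """One completed 320-trial session played by a biased M7 agent."""
    session = make_session(TaskConfig(), rng=np.random.default_rng(7))
    return simulate_subject(session, m7_params, rng=np.random.default_rng(8)).trials


def random_params(spec, rng, scale=0.8):
    """Random unconstrained parameter vector of moderate magnitude."""
    return ParameterVector(spec, rng.normal(0.0, scale, size=spec.n_params))
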