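"""Shared fixtures: small analytic toy models and the reference model."""

import numpy as np
import pytest

from trajoed.ode import Experiment, OdeModel


def make_decay_model(rtol=1e-9, atol=1e-12) -> OdeModel:
    """1-state exponential decay dx/dt = -k x, x0 = 1, output = x.
    Closed form x(t) = exp(-k t) makes it the analytic oracle model."""
    return OdeModel(
        name="decay",
        state_names=("x",),
        output_names=("x",),
        param_names=("k",),
        fixed_params={},
        vector_field=lambda x, u, k, t: -k * x,
        output_map=lambda s: np.asarray(s),
        initial_state=lambda u, k: np.array([1.0]),
        rtol=rtol,
        atol=atol,
    )


def make_cascade_model(b=1.0, rtol=1e-8, atol=1e-10) -> OdeModel:
    """3-parameter linear cascade: constant production of A, conversions
    A -> B -> C, loss of C; every species observable.  Identifiable from
    dense data on all three outputs."""

    def rhs(x, u, k, t):
        a, bb, c = x
        k1, k2, k3 = k
        return np.array([b - k1 * a, k1 * a - k2 * bb, k2 * bb - k3 * c])

    def x0(u, k):
        # start well below steady state so the transient carries rate
        # information, not just the asymptotic levels
        return np.array([0.2, 0.2, 0.2])

    return OdeModel(
        name="cascade",
        state_names=("A", "B", "C"),
        output_names=("A", "B", "C"),
        param_names=("k1", "k2", "k3"),
        fixed_params={"b": b},
        vector_field=rhs,
        output_map=lambda s: np.asarray(s),
        initial_state=x0,
        rtol=rtol,
        atol=atol,
    )


@pytest.fixture
def decay_model():
    return make_decay_model()


@pytest.fixture
def decay_experiment():
    return Experiment(
        index=1,
        input=(1.0,),
        outputs=("x",),
        time_grid=tuple(np.linspace(0.25, 8.0, 32)),
    )


@pytest.fixture
def cascade_model():
    return make_cascade_model()


@pytest.fixture
def cascade_experiment():
    return Experiment(
        index=1,
        input=(1.0,),
        outputs=("A", "B", "C"),
        time_grid=tuple(np.linspace(0.5, 24.0, 48)),
    )


@pytest.fixture(scope="session")
def golgi_model():
    from trajoed.golgi import trans_golgi_model

    # slightly relaxed tolerances keep the suite responsive; accuracy is
    # still far below measurement noise
    return trans_golgi_model(rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def golgi_catalogue():
    from trajoed.golgi import trans_golgi_catalogue

    return trans_golgi_catalogue()
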