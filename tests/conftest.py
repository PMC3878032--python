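import numpy as np
import pytest
from hypothesis import settings

from kfprog.params import StateSpaceParams
from kfprog.simulate import SimConfig, default_sim_params, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return default_sim_params()


@pytest.fixture(scope="session")
def small_cohort():
    """50-patient simulated cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(n_patients=50, seed=11))


@pytest.fixture()
def scalar_params():
    """Scalar local-level model: T=1, Q=0.5, H=1, R=1."""
    return StateSpaceParams(T=[[1.0]], Q=[[0.5]], H=[[1.0]], R=[[1.0]],
                            initial_mean=[0.0], initial_cov=[[2.0]])


def toy_systems():
    """Small state-space systems (<= 3 dims, varied H/R) for oracle checks."""
    rng = np.random.default_rng(123)
    systems = []
    # scalar random walk
    systems.append(StateSpaceParams(T=[[1.0]], Q=[[0.5]], H=[[1.0]], R=[[1.0]],
                                    initial_mean=[0.5], initial_cov=[[2.0]]))
    # 2-dim local linear trend, level observed
    systems.append(StateSpaceParams(
        T=[[1.0, 1.0], [0.0, 1.0]], Q=np.diag([0.2, 0.05]),
        H=[[1.0, 0.0]], R=[[0.8]],
        initial_mean=[1.0, -0.3], initial_cov=np.diag([1.0, 0.1])))
    # 3-dim with full random observation and correlated Q
    A = rng.normal(size=(3, 3))
    Q = 0.1 * (A @ A.T) + 0.05 * np.eye(3)
    B = rng.normal(size=(3, 3))
    R = 0.2 * (B @ B.T) + 0.1 * np.eye(3)
    systems.append(StateSpaceParams(
        T=0.9 * np.eye(3) + 0.05 * rng.normal(size=(3, 3)),
        Q=Q, H=rng.normal(size=(3, 3)), R=R,
        initial_mean=rng.normal(size=3), initial_cov=np.eye(3)))
    # 3-dim state, 2-dim observation (rectangular H)
    systems.append(StateSpaceParams(
        T=[[1.0, 1.0, 0.0], [0.0, 1.0, 1.0], [0.0, 0.0, 0.5]],
        Q=np.diag([0.1, 0.02, 0.005]),
        H=[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], R=np.diag([0.5, 0.3]),
        initial_mean=[0.0, 0.1, 0.0], initial_cov=np.diag([2.0, 0.2, 0.05])))
    return systems


def simulate_observations(params, n_visits, rng, missing=None):
    """Draw one trajectory's observations from a state-space model."""
    n, m = params.n, params.m
    L0 = np.linalg.cholesky(params.initial_cov + 1e-12 * np.eye(n))
    LQ = np.linalg.cholesky(params.Q + 1e-12 * np.eye(n))
    LR = np.linalg.cholesky(params.R + 1e-12 * np.eye(m))
    x = params.initial_mean + L0 @ rng.standard_normal(n)
    Z = np.empty((n_visits, m))
    for j in range(n_visits):
        if j > 0:
            x = params.T @ x + LQ @ rng.standard_normal(n)
        Z[j] = params.H @ x + LR @ rng.standard_normal(m)
    if missing is not None:
        for (j, c) in missing:
            Z[j, c] = np.nan
    return Z
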