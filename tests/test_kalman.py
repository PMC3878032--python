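"""Filter, smoother and likelihood checks against joint-Gaussian oracles."""

import numpy as np
import pytest

from kfprog.kalman import (
    StateBelief,
    filter_series,
    kalman_predict,
    kalman_update,
    log_likelihood,
    smooth_series,
    finite_difference_observations,
)
from kfprog.params import StateSpaceParams

from _oracles import (
    oracle_filtered_moments,
    oracle_loglik,
    oracle_smoothed_moments,
)
from conftest import simulate_observations, toy_systems


def test_predict_identity_dynamics_is_noop():
    params = StateSpaceParams(T=np.eye(2), Q=np.zeros((2, 2)),
                              H=np.eye(2), R=np.eye(2),
                              initial_mean=[0, 0], initial_cov=np.eye(2))
    belief = StateBelief(mean=[1.0, -2.0], cov=[[0.5, 0.1], [0.1, 0.3]])
    out = kalman_predict(belief, params)
    np.testing.assert_allclose(out.mean, belief.mean)
    np.testing.assert_allclose(out.cov, belief.cov)
    assert out.kind == "predicted"


def test_predict_local_linear_trend_mean():
    params = StateSpaceParams(T=[[1, 1], [0, 1]], Q=np.zeros((2, 2)),
                              H=np.eye(2), R=np.eye(2),
                              initial_mean=[0, 0], initial_cov=np.eye(2))
    out = kalman_predict(StateBelief(mean=[1.0, 0.5], cov=np.eye(2)), params)
    np.testing.assert_allclose(out.mean, [1.5, 0.5])


def test_predict_covariance_matches_monte_carlo(default_params):
    rng = np.random.default_rng(5)
    mean = rng.normal(size=9)
    A = rng.normal(size=(9, 9))
    cov = A @ A.T / 9 + 0.5 * np.eye(9)
    out = kalman_predict(StateBelief(mean=mean, cov=cov), default_params)
    draws = 10 ** 6
    x = mean + rng.standard_normal((draws, 9)) @ np.linalg.cholesky(cov).T
    w = rng.standard_normal((draws, 9)) @ np.sqrt(default_params.Q)
    y = x @ default_params.T.T + w
    mc_cov = np.cov(y.T)
    # Monte-Carlo sampling error ~ O(1/sqrt(draws)) on unit-scale entries
    assert np.max(np.abs(mc_cov - out.cov)) < 0.02 * np.max(np.abs(out.cov))


def test_update_exact_observation_recovers_z():
    params = StateSpaceParams(T=np.eye(2), Q=np.eye(2), H=np.eye(2),
                              R=1e-14 * np.eye(2),
                              initial_mean=[0, 0], initial_cov=np.eye(2))
    belief = StateBelief(mean=[0.0, 0.0], cov=np.eye(2), kind="predicted")
    out = kalman_update(belief, np.array([1.5, -0.5]), params)
    np.testing.assert_allclose(out.mean, [1.5, -0.5], atol=1e-6)


def test_update_uninformative_observation_keeps_prior():
    params = StateSpaceParams(T=np.eye(1), Q=np.eye(1), H=np.eye(1),
                              R=[[1e12]], initial_mean=[0], initial_cov=np.eye(1))
    belief = StateBelief(mean=[2.0], cov=[[1.0]], kind="predicted")
    out = kalman_update(belief, np.array([100.0]), params)
    np.testing.assert_allclose(out.mean, [2.0], atol=1e-6)
    np.testing.assert_allclose(out.cov, [[1.0]], atol=1e-6)


def test_update_matches_gaussian_conditioning_oracle():
    """Scalar toy: posterior after one observation equals direct conditioning
    of the joint (alpha, z) Gaussian."""
    params = StateSpaceParams(T=[[1.0]], Q=[[1.0]], H=[[1.0]], R=[[1.0]],
                              initial_mean=[0.0], initial_cov=[[1.0]])
    z = np.array([[2.0]])
    fs = filter_series(z, params)
    mo, co = oracle_filtered_moments(params, z)
    np.testing.assert_allclose(fs.means, mo, atol=1e-10)
    np.testing.assert_allclose(fs.covs, co, atol=1e-10)


def test_single_visit_series_is_update_of_initial_belief(scalar_params):
    fs = filter_series(np.array([[1.3]]), scalar_params)
    prior = StateBelief(mean=scalar_params.initial_mean,
                        cov=scalar_params.initial_cov, kind="predicted")
    upd = kalman_update(prior, np.array([1.3]), scalar_params)
    np.testing.assert_allclose(fs.means[0], upd.mean)
    np.testing.assert_allclose(fs.covs[0], upd.cov)


def test_all_missing_series_is_prediction_rollout(scalar_params):
    Z = np.full((4, 1), np.nan)
    fs = filter_series(Z, scalar_params)
    mean, cov = scalar_params.initial_mean, scalar_params.initial_cov
    for j in range(4):
        np.testing.assert_allclose(fs.means[j], mean)
        np.testing.assert_allclose(fs.covs[j], cov)
        mean = scalar_params.T @ mean
        cov = scalar_params.T @ cov @ scalar_params.T.T + scalar_params.Q
    assert fs.loglik == 0.0


@pytest.mark.parametrize("params", toy_systems())
@pytest.mark.parametrize("n_visits,missing", [
    (1, None), (3, None), (4, None), (4, "some"),
])
def test_filter_matches_prefix_conditioning_oracle(params, n_visits, missing):
    """Filtered moments equal conditioning alpha_j on observations 0..j."""
    rng = np.random.default_rng(42)
    miss = None
    if missing == "some":
        miss = [(1, 0), (2, params.m - 1)]
    Z = simulate_observations(params, n_visits, rng, missing=miss)
    fs = filter_series(Z, params)
    mo, co = oracle_filtered_moments(params, Z)
    np.testing.assert_allclose(fs.means, mo, atol=1e-8)
    np.testing.assert_allclose(fs.covs, co, atol=1e-8)


@pytest.mark.parametrize("params", toy_systems())
@pytest.mark.parametrize("n_visits,missing", [(3, None), (4, "some")])
def test_smoother_matches_full_conditioning_oracle(params, n_visits, missing):
    """Smoothed moments (and lag-one covariances) equal conditioning every
    state on all observations at once."""
    rng = np.random.default_rng(7)
    miss = [(0, 0)] if missing == "some" else None
    Z = simulate_observations(params, n_visits, rng, missing=miss)
    fs = filter_series(Z, params)
    ss = smooth_series(fs, params)
    mo, co, lag = oracle_smoothed_moments(params, Z, lag_one=True)
    np.testing.assert_allclose(ss.means, mo, atol=1e-8)
    np.testing.assert_allclose(ss.covs, co, atol=1e-8)
    np.testing.assert_allclose(ss.lag_one[1:], lag[1:], atol=1e-8)


def test_smoother_last_visit_equals_filtered(scalar_params):
    rng = np.random.default_rng(3)
    Z = simulate_observations(scalar_params, 5, rng)
    fs = filter_series(Z, scalar_params)
    ss = smooth_series(fs, scalar_params)
    np.testing.assert_allclose(ss.means[-1], fs.means[-1])
    np.testing.assert_allclose(ss.covs[-1], fs.covs[-1])


def test_smoother_deterministic_dynamics_lie_on_trajectory():
    """With Q = 0 the smoothed means follow the deterministic recursion."""
    params = StateSpaceParams(T=[[1.0, 1.0], [0.0, 1.0]], Q=np.zeros((2, 2)),
                              H=[[1.0, 0.0]], R=[[0.5]],
                              initial_mean=[0.0, 0.2], initial_cov=np.eye(2))
    rng = np.random.default_rng(9)
    Z = simulate_observations(params, 6, rng)
    ss = smooth_series(filter_series(Z, params), params)
    for j in range(1, 6):
        np.testing.assert_allclose(ss.means[j], params.T @ ss.means[j - 1],
                                   atol=1e-8)


def test_loglik_empty_cohort_is_zero(scalar_params):
    from kfprog.kalman import log_likelihood
    assert log_likelihood([], scalar_params) == 0.0


def test_loglik_single_scalar_visit_closed_form():
    """One visit, total variance initial_cov + R = 2, z = 0."""
    params = StateSpaceParams(T=[[1.0]], Q=[[0.0]], H=[[1.0]], R=[[1.0]],
                              initial_mean=[0.0], initial_cov=[[1.0]])
    ll = log_likelihood([np.array([[0.0]])], params)
    expected = -0.5 * (np.log(2 * np.pi) + np.log(2.0))
    np.testing.assert_allclose(ll, expected, atol=1e-12)


@pytest.mark.parametrize("params", toy_systems())
def test_loglik_matches_joint_density_oracle(params):
    rng = np.random.default_rng(17)
    Z = simulate_observations(params, 4, rng, missing=[(1, 0)])
    ll = log_likelihood([Z], params)
    np.testing.assert_allclose(ll, oracle_loglik(params, Z), atol=1e-8)


def test_emitted_covariances_symmetric_psd(default_params, small_cohort):
    for p in small_cohort.patients[:10]:
        fs = filter_series(p, default_params)
        ss = smooth_series(fs, default_params)
        for covs in (fs.covs, fs.pred_covs, ss.covs):
            for C in covs:
                np.testing.assert_allclose(C, C.T, atol=1e-10)
                assert np.linalg.eigvalsh(C).min() >= -1e-10


def test_finite_difference_observations_masks_leading_visits():
    levels = np.array([[-2.0, 3.0, 18.0], [-3.0, 3.5, 17.0], [-4.0, 3.0, 16.5]])
    out = finite_difference_observations(levels)
    assert np.all(np.isnan(out[0, [1, 2, 4, 5, 7, 8]]))
    assert np.all(np.isnan(out[1, [2, 5, 8]]))
    np.testing.assert_allclose(out[1, 1], -1.0)   # MD velocity
    np.testing.assert_allclose(out[2, 2], 0.0)    # MD acceleration
    np.testing.assert_allclose(out[:, 0], levels[:, 0])
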