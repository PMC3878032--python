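"""GEE building blocks and the full fit against independent oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import norm

from kfprog.gee import (
    GEEError,
    RegressionData,
    bernoulli_variance,
    estimate_rho,
    gee_fit,
    inverse_logit,
    logit_link,
    predict_probability,
    wald_chisq,
    working_correlation,
)


def test_logit_pair_identities():
    assert logit_link(0.5) == 0.0
    np.testing.assert_allclose(inverse_logit(logit_link(0.3)), 0.3, atol=1e-12)
    np.testing.assert_allclose(inverse_logit(np.log(3.0)), 0.75, atol=1e-12)


def test_logit_rejects_boundary():
    with pytest.raises(ValueError):
        logit_link(1.0)
    with pytest.raises(ValueError):
        bernoulli_variance(0.0)


def test_bernoulli_variance_values_and_symmetry():
    assert bernoulli_variance(0.5) == 0.25
    np.testing.assert_allclose(bernoulli_variance(0.1), 0.09, atol=1e-15)
    mu = np.random.default_rng(1).uniform(0.01, 0.99, 100)
    np.testing.assert_allclose(bernoulli_variance(mu),
                               bernoulli_variance(1.0 - mu), atol=1e-15)


def test_working_correlation_identity_and_gaps():
    np.testing.assert_array_equal(working_correlation([1, 2, 3], 0.0), np.eye(3))
    M = working_correlation([0, 2], 0.5)
    np.testing.assert_allclose(M[0, 1], 0.25)
    M = working_correlation([1, 2, 4], 0.5)
    np.testing.assert_allclose([M[0, 1], M[0, 2], M[1, 2]], [0.5, 0.125, 0.25])
    with pytest.raises(ValueError):
        working_correlation([0, 1], 1.0)


def test_estimate_rho_perfect_correlation_clips():
    e = np.array([1.0, 1.0, -1.0, -1.0])
    rho = estimate_rho(e, np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))
    assert rho == pytest.approx(0.99)


def test_estimate_rho_iid_null_near_zero():
    rng = np.random.default_rng(8)
    n_clusters, size = 5000, 3
    e = rng.standard_normal(n_clusters * size)
    clusters = np.repeat(np.arange(n_clusters), size)
    times = np.tile(np.arange(size), n_clusters)
    rho = estimate_rho(e, clusters, times)
    # ~1e4 pairs -> SE about 1/sqrt(n_pairs)
    assert abs(rho) < 3.0 / np.sqrt(2 * n_clusters)


def test_estimate_rho_hand_example():
    """2 clusters x 2 visits: mean(e1*e2) / mean(e^2) evaluated by hand."""
    e = np.array([1.0, 0.5, -1.0, 0.5])
    num = (1.0 * 0.5 + (-1.0) * 0.5) / 2.0      # = 0
    scale = np.mean(e ** 2)
    expected = num / scale
    rho = estimate_rho(e, np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))
    assert rho == pytest.approx(expected)


def _logistic_data(n, beta, rng):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, len(beta) - 1))])
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < mu).astype(float)
    return X, y


def test_size_one_clusters_reproduce_logistic_mle():
    """With independent singleton clusters the GEE equations reduce to the
    ordinary logistic score equations."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(12)
    X, y = _logistic_data(800, np.array([-0.5, 1.0, -0.7]), rng)
    data = RegressionData(X=X, y=y, cluster=np.arange(800),
                          time=np.zeros(800, dtype=int))
    for corstr in ("ar1", "independence"):
        fit = gee_fit(data, corstr=corstr)
        mle = sm.Logit(y, X).fit(disp=0, tol=1e-12)
        np.testing.assert_allclose(fit.beta, mle.params, atol=1e-6)


def _ar1_binary_cohort(n_clusters, n_visits, beta, rho_lat, rng):
    """Latent-threshold generator: y = 1{Phi(u) < mu} with AR(1) latent u,
    so marginal P(y=1 | x) is exactly expit(x'beta)."""
    rows_X, rows_y, rows_c, rows_t = [], [], [], []
    for i in range(n_clusters):
        x = rng.normal(size=(n_visits, len(beta) - 1))
        X = np.column_stack([np.ones(n_visits), x])
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        u = np.empty(n_visits)
        u[0] = rng.standard_normal()
        for j in range(1, n_visits):
            u[j] = rho_lat * u[j - 1] + np.sqrt(1 - rho_lat ** 2) * rng.standard_normal()
        y = (norm.cdf(u) < mu).astype(float)
        rows_X.append(X); rows_y.append(y)
        rows_c.append(np.full(n_visits, i)); rows_t.append(np.arange(n_visits))
    return RegressionData(X=np.vstack(rows_X), y=np.concatenate(rows_y),
                          cluster=np.concatenate(rows_c),
                          time=np.concatenate(rows_t))


def test_independence_equals_ar1_with_rho_fixed_zero():
    rng = np.random.default_rng(21)
    data = _ar1_binary_cohort(80, 6, np.array([-0.8, 0.9]), 0.4, rng)
    f1 = gee_fit(data, corstr="independence")
    f2 = gee_fit(data, corstr="ar1", fix_rho=0.0)
    np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-10)


def test_null_covariate_coefficient_near_zero():
    """A covariate independent of a balanced response stays within 3 robust
    SEs of zero at n = 10^4."""
    rng = np.random.default_rng(31)
    n = 10 ** 4
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = (rng.random(n) < 0.5).astype(float)
    data = RegressionData(X=X, y=y, cluster=np.arange(n),
                          time=np.zeros(n, dtype=int))
    fit = gee_fit(data, corstr="independence")
    assert abs(fit.beta[1]) < 3.0 * fit.robust_se[1]


def test_sandwich_psd_and_relabeling_invariance():
    rng = np.random.default_rng(41)
    data = _ar1_binary_cohort(60, 5, np.array([-0.5, 0.8, -0.4]), 0.3, rng)
    fit = gee_fit(data, corstr="ar1")
    assert np.linalg.eigvalsh(fit.robust_cov).min() >= -1e-12
    # permute cluster labels: fit must be unchanged
    mapping = {c: f"relabeled_{c}" for c in np.unique(data.cluster)}
    relabeled = RegressionData(
        X=data.X, y=data.y,
        cluster=np.array([mapping[c] for c in data.cluster]),
        time=data.time)
    fit2 = gee_fit(relabeled, corstr="ar1")
    np.testing.assert_allclose(fit.beta, fit2.beta, atol=1e-12)
    np.testing.assert_allclose(fit.robust_cov, fit2.robust_cov, atol=1e-12)


def test_estimating_equations_residual_small_at_convergence():
    rng = np.random.default_rng(51)
    data = _ar1_binary_cohort(100, 8, np.array([-1.0, 0.7]), 0.4, rng)
    fit = gee_fit(data, corstr="ar1", tol=1e-10)
    assert fit.converged
    # recompute the estimating function at the solution
    mu = inverse_logit(data.X @ fit.beta)
    a = mu * (1.0 - mu)
    g = np.zeros(len(fit.beta))
    for cid in np.unique(data.cluster):
        m = data.cluster == cid
        Xi, ri = data.X[m], (data.y - mu)[m]
        Vi = np.outer(np.sqrt(a[m]), np.sqrt(a[m])) * \
            working_correlation(data.time[m], fit.rho)
        g += (Xi * a[m][:, None]).T @ np.linalg.solve(Vi, ri)
    assert np.max(np.abs(g)) < 1e-4


def test_predict_probability_contracts():
    fit_like = gee_fit(
        RegressionData(X=np.column_stack([np.ones(40),
                                          np.random.default_rng(3).normal(size=40)]),
                       y=np.tile([0.0, 1.0], 20),
                       cluster=np.arange(40), time=np.zeros(40, dtype=int)),
        corstr="independence")
    fit_like.beta = np.array([np.log(3.0), 0.0])
    assert predict_probability(fit_like, [1.0, 5.0]) == pytest.approx(0.75)
    fit_like.beta = np.zeros(2)
    assert predict_probability(fit_like, [1.0, -2.0]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        predict_probability(fit_like, [1.0, 0.0, 0.0])
    # monotone in a positive-coefficient covariate
    fit_like.beta = np.array([0.0, 1.5])
    grid = np.column_stack([np.ones(50), np.linspace(-3, 3, 50)])
    p = predict_probability(fit_like, grid)
    assert np.all(np.diff(p) >= 0)


def test_wald_chisq_anchors():
    rng = np.random.default_rng(61)
    data = _ar1_binary_cohort(50, 4, np.array([-0.5, 0.5]), 0.2, rng)
    fit = gee_fit(data)
    fit.beta = fit.beta.copy()
    fit.beta[1] = 0.0
    stat, p = wald_chisq(fit, 1)
    assert stat == 0.0 and p == 1.0
    # chi2(1) anchor: statistic 3.841 ~ p 0.05
    fit.beta[1] = np.sqrt(3.841 * fit.robust_cov[1, 1])
    stat, p = wald_chisq(fit, 1)
    assert p == pytest.approx(stats.chi2.sf(3.841, 1), abs=1e-12)
    assert p == pytest.approx(0.05, abs=2e-4)


def test_rank_deficient_design_raises():
    X = np.column_stack([np.ones(20), np.ones(20)])
    data = RegressionData(X=X, y=np.tile([0.0, 1.0], 10),
                          cluster=np.arange(20), time=np.zeros(20, dtype=int))
    with pytest.raises(GEEError):
        gee_fit(data)
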