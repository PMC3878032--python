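"""Independent oracles used by the test suite.

These deliberately avoid the package's recursive implementations: the
state-space oracle builds the full joint Gaussian over stacked states
and observations and conditions it directly; the label oracle is a
literal double loop over (j, k); the AUC oracle counts concordant pairs.
"""

from __future__ import annotations

import numpy as np


def joint_state_obs_gaussian(params, n_visits: int):
    """Mean and covariance of (alpha_0..alpha_J, z_0..z_J) stacked.

    States follow alpha_j = T alpha_{j-1} + w_j; observations
    z_j = H alpha_j + v_j.  Everything is jointly Gaussian, so the
    stacked moments are linear-algebraic.
    """
    n, m = params.n, params.m
    J = n_visits
    dim_a = n * J
    # alpha = A @ [alpha_0; w_1..w_{J-1}] — build covariance by propagation
    mean_a = np.zeros(dim_a)
    cov_a = np.zeros((dim_a, dim_a))
    means = [params.initial_mean]
    for j in range(1, J):
        means.append(params.T @ means[-1])
    for j in range(J):
        mean_a[j * n:(j + 1) * n] = means[j]
    # Cov(alpha_j, alpha_k) for j <= k: Var_j @ (T^{k-j})'
    var = [params.initial_cov]
    for j in range(1, J):
        var.append(params.T @ var[-1] @ params.T.T + params.Q)
    powers = [np.eye(n)]
    for j in range(1, J):
        powers.append(params.T @ powers[-1])
    for j in range(J):
        for k in range(j, J):
            block = var[j] @ powers[k - j].T  # Cov(alpha_j, alpha_k)
            cov_a[j * n:(j + 1) * n, k * n:(k + 1) * n] = block
            cov_a[k * n:(k + 1) * n, j * n:(j + 1) * n] = block.T
    # observations: z = (I_J kron H) alpha + noise
    Hbig = np.kron(np.eye(J), params.H)
    Rbig = np.kron(np.eye(J), params.R)
    mean_z = Hbig @ mean_a
    cov_z = Hbig @ cov_a @ Hbig.T + Rbig
    cov_az = cov_a @ Hbig.T
    mean = np.concatenate([mean_a, mean_z])
    cov = np.block([[cov_a, cov_az], [cov_az.T, cov_z]])
    return mean, cov


def condition_gaussian(mean, cov, obs_idx, obs_values):
    """Condition N(mean, cov) on components obs_idx == obs_values."""
    all_idx = np.arange(len(mean))
    free = np.setdiff1d(all_idx, obs_idx)
    S_oo = cov[np.ix_(obs_idx, obs_idx)]
    S_fo = cov[np.ix_(free, obs_idx)]
    resid = obs_values - mean[obs_idx]
    sol = np.linalg.solve(S_oo, np.column_stack([resid, S_fo.T]))
    mean_c = mean[free] + S_fo @ sol[:, 0]
    cov_c = cov[np.ix_(free, free)] - S_fo @ sol[:, 1:]
    return mean_c, 0.5 * (cov_c + cov_c.T), free


def oracle_filtered_moments(params, Z):
    """Per-visit filtered moments by prefix conditioning of the joint Gaussian.

    Z is (J, m) with NaN for missing; the filtered belief at visit j
    conditions alpha_j on the observed components of z_0..z_j.
    """
    J = len(Z)
    n, m = params.n, params.m
    mean, cov = joint_state_obs_gaussian(params, J)
    z_flat = np.asarray(Z, dtype=float).reshape(-1)
    means_out, covs_out = [], []
    for j in range(J):
        upto = (j + 1) * m
        obs_idx = n * J + np.nonzero(np.isfinite(z_flat[:upto]))[0]
        state_idx = np.arange(j * n, (j + 1) * n)
        if len(obs_idx) == 0:
            means_out.append(mean[state_idx])
            covs_out.append(cov[np.ix_(state_idx, state_idx)])
            continue
        mean_c, cov_c, free = condition_gaussian(
            mean, cov, obs_idx, z_flat[np.isfinite(z_flat[:upto])
                                       .nonzero()[0]])
        pos = np.searchsorted(free, state_idx)
        means_out.append(mean_c[pos])
        covs_out.append(cov_c[np.ix_(pos, pos)])
    return np.array(means_out), np.array(covs_out)


def oracle_smoothed_moments(params, Z, lag_one: bool = False):
    """Smoothed moments by conditioning every state on ALL observations."""
    J = len(Z)
    n, m = params.n, params.m
    mean, cov = joint_state_obs_gaussian(params, J)
    z_flat = np.asarray(Z, dtype=float).reshape(-1)
    finite = np.isfinite(z_flat)
    obs_idx = n * J + np.nonzero(finite)[0]
    mean_c, cov_c, free = condition_gaussian(mean, cov, obs_idx, z_flat[finite])
    means_out = np.empty((J, n))
    covs_out = np.empty((J, n, n))
    for j in range(J):
        state_idx = np.arange(j * n, (j + 1) * n)
        pos = np.searchsorted(free, state_idx)
        means_out[j] = mean_c[pos]
        covs_out[j] = cov_c[np.ix_(pos, pos)]
    if not lag_one:
        return means_out, covs_out
    lag = np.zeros((J, n, n))
    for j in range(1, J):
        pos_j = np.searchsorted(free, np.arange(j * n, (j + 1) * n))
        pos_prev = np.searchsorted(free, np.arange((j - 1) * n, j * n))
        lag[j] = cov_c[np.ix_(pos_j, pos_prev)]
    return means_out, covs_out, lag


def oracle_loglik(params, Z):
    """Joint Gaussian density of the observed components of Z."""
    from scipy.stats import multivariate_normal

    J = len(Z)
    n = params.n
    mean, cov = joint_state_obs_gaussian(params, J)
    z_flat = np.asarray(Z, dtype=float).reshape(-1)
    finite = np.isfinite(z_flat)
    idx = n * J + np.nonzero(finite)[0]
    return float(multivariate_normal(
        mean[idx], cov[np.ix_(idx, idx)], allow_singular=False
    ).logpdf(z_flat[finite]))


def brute_force_labels(md, definition: str = "composite"):
    """Literal (j, k) double-loop progression labeler over one MD series."""
    md = np.asarray(md, dtype=float)
    J = len(md)

    def stage(v):
        if v > -6.0:
            return 0
        if v > -12.0:
            return 1
        return 2

    labels = np.zeros(J)
    base = md[0]
    for j in range(1, J):
        if not np.isfinite(md[j]):
            labels[j] = np.nan
            continue
        md_fire = False
        if base - md[j] >= 3.0:
            for k in range(j + 1, J):
                if np.isfinite(md[k]) and base - md[k] >= 3.0:
                    md_fire = True
                    break
        hap_fire = stage(md[j]) > stage(base)
        if definition == "md_only":
            labels[j] = float(md_fire)
        elif definition == "hap_only":
            labels[j] = float(hap_fire)
        else:
            labels[j] = float(md_fire or hap_fire)
    return labels


def mann_whitney_auc(scores, labels):
    """Concordance-probability AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))
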