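"""EM estimation of shared population state-space parameters.

Standard linear-Gaussian EM (Shumway-Stoffer): the E-step runs the
Kalman filter and RTS smoother per patient and pools the smoothed
sufficient statistics; the M-step applies closed-form updates for the
requested parameter subset.  Parameters are population-shared —
personalization enters only through per-patient filtering.

By default the structural transition matrix T stays fixed (an
unrestricted 9x9 transition is weakly identified at realistic cohort
sizes) and EM estimates {Q, R, initial_mean, initial_cov}.  When some
observation components are missing, the R update is restricted to its
diagonal, computed per observed component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, PatientSeries
from .kalman import filter_series, smooth_series, _series_observations
from .params import StateSpaceParams

DEFAULT_ESTIMATE = ("Q", "R", "initial_mean", "initial_cov")
_ALLOWED = {"T", "Q", "R", "initial_mean", "initial_cov"}
_ASCENT_TOL = 1e-8


class EMError(RuntimeError):
    pass


@dataclass
class EMResult:
    params: StateSpaceParams
    loglik_trace: list[float]
    converged: bool
    n_iter: int


def _sym(mat):
    return 0.5 * (mat + mat.T)


def _cohort_series(cohort, params) -> list[np.ndarray]:
    out = []
    for series in cohort:
        if isinstance(series, PatientSeries):
            out.append(_series_observations(series, params))
        else:
            out.append(np.asarray(series, dtype=float))
    return out


def em_fit(cohort, init: StateSpaceParams,
           estimate: tuple[str, ...] = DEFAULT_ESTIMATE,
           tol: float = 1e-6, max_iter: int = 200) -> EMResult:
    """Fit the selected parameter subset by EM.

    Parameters
    ----------
    cohort : Cohort or iterable of (J, m) observation arrays.
    init : starting parameters (also supplies fixed components).
    estimate : subset of {"T", "Q", "R", "initial_mean", "initial_cov"}.
        Empty -> returns ``init`` unchanged with a length-1 trace.
    tol : relative log-likelihood change at which to stop.
    max_iter : iteration cap.

    The log-likelihood trace is non-decreasing up to a 1e-8 relative
    tolerance; a larger decrease raises :class:`EMError` (it would
    indicate a smoother defect, not a data problem).
    """
    bad = set(estimate) - _ALLOWED
    if bad:
        raise ValueError(f"unknown parameters to estimate: {sorted(bad)}")
    series_list = _cohort_series(cohort, init)
    if not series_list:
        raise EMError("EM requires at least one patient")
    n_trans = sum(max(len(Z) - 1, 0) for Z in series_list)
    if not estimate:
        ll = sum(filter_series(Z, init).loglik for Z in series_list)
        return EMResult(params=init, loglik_trace=[ll], converged=True, n_iter=0)
    if ("Q" in estimate or "T" in estimate) and n_trans < 2:
        raise EMError("estimating Q or T needs at least 2 state transitions")
    if not any(len(Z) >= 2 for Z in series_list):
        raise EMError("EM requires at least one patient with >= 2 visits")

    params = init
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        params, ll = _em_step(series_list, params, estimate)
        if trace:
            prev = trace[-1]
            if ll < prev - _ASCENT_TOL * (abs(prev) + 1.0):
                raise EMError(
                    f"log-likelihood decreased at iteration {it} "
                    f"({prev:.8g} -> {ll:.8g}); smoother inconsistency")
            if abs(ll - prev) < tol * (abs(prev) + 1.0):
                trace.append(ll)
                converged = True
                break
        trace.append(ll)
    return EMResult(params=params, loglik_trace=trace, converged=converged, n_iter=it)


def _em_step(series_list, params: StateSpaceParams, estimate):
    """One E + M step; returns (new_params, loglik at the *input* params)."""
    n, m = params.n, params.m
    H, T = params.H, params.T

    loglik = 0.0
    S11 = np.zeros((n, n))
    S10 = np.zeros((n, n))
    S00 = np.zeros((n, n))
    n_trans = 0
    m0_list = []
    P0_sum = np.zeros((n, n))
    # R statistics
    any_missing = any(not np.all(np.isfinite(Z)) for Z in series_list)
    R_full = np.zeros((m, m))
    r_diag = np.zeros(m)
    r_count_full = 0
    r_count_diag = np.zeros(m)

    for Z in series_list:
        fs = filter_series(Z, params)
        loglik += fs.loglik
        ss = smooth_series(fs, params)
        ms, Ps, C = ss.means, ss.covs, ss.lag_one
        J = len(ms)
        m0_list.append(ms[0])
        P0_sum += Ps[0]
        if J >= 2:
            E_tt = Ps + np.einsum("ji,jk->jik", ms, ms)
            S11 += E_tt[1:].sum(axis=0)
            S00 += E_tt[:-1].sum(axis=0)
            S10 += (C[1:] + np.einsum("ji,jk->jik", ms[1:], ms[:-1])).sum(axis=0)
            n_trans += J - 1
        if "R" in estimate:
            if any_missing:
                finite = np.isfinite(Z)
                resid = Z - ms @ H.T
                HPs = np.einsum("ik,jkl,ml->jim", H, Ps, H)  # (J, m, m)
                hvar = np.diagonal(HPs, axis1=1, axis2=2)
                vals = np.where(finite, resid ** 2 + hvar, 0.0)
                r_diag += vals.sum(axis=0)
                r_count_diag += finite.sum(axis=0)
            else:
                resid = Z - ms @ H.T
                R_full += resid.T @ resid
                R_full += np.einsum("ik,jkl,ml->im", H, Ps, H)
                r_count_full += J

    new = {}
    if "T" in estimate:
        T_new = np.linalg.solve(S00.T, S10.T).T
        new["T"] = T_new
        T_for_Q = T_new
    else:
        T_for_Q = T
    if "Q" in estimate:
        Q = (S11 - T_for_Q @ S10.T - S10 @ T_for_Q.T
             + T_for_Q @ S00 @ T_for_Q.T) / n_trans
        new["Q"] = _clip_psd(_sym(Q))
    if "R" in estimate:
        if any_missing:
            counts = np.maximum(r_count_diag, 1.0)
            new["R"] = np.diag(r_diag / counts)
        else:
            new["R"] = _clip_psd(_sym(R_full / r_count_full))
    if "initial_mean" in estimate or "initial_cov" in estimate:
        m0 = np.vstack(m0_list)
        mu0 = m0.mean(axis=0)
        if "initial_mean" in estimate:
            new["initial_mean"] = mu0
        if "initial_cov" in estimate:
            centered = m0 - mu0
            P0 = (P0_sum + centered.T @ centered) / len(m0_list)
            new["initial_cov"] = _clip_psd(_sym(P0))
    return params.replace(**new), loglik


def _clip_psd(mat: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Clip negligible negative eigenvalues arising from round-off."""
    eigval, eigvec = np.linalg.eigh(mat)
    if eigval.min() >= floor:
        return mat
    eigval = np.clip(eigval, floor, None)
    return _sym(eigvec @ np.diag(eigval) @ eigvec.T)
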