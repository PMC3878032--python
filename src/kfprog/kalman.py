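"""Kalman filtering and RTS smoothing for per-patient biomarker series.

The filter runs the usual predict/update recursion over a patient's
visits.  Missing observation components (NaN) are handled by restricting
the observation equation to the observed rows; a fully missing visit
degenerates to a pure prediction step.  The update uses the Joseph form
so emitted covariances stay symmetric PSD, and the filter accumulates
the Gaussian prediction-error log-likelihood that the EM routine
maximizes.

Two observation conventions are supported:

* levels-only (m = 3): the filter sees the measured MD/PSD/IOP levels
  and infers velocities and accelerations as latent state;
* identity (m = 9): finite-differenced velocity/acceleration
  pseudo-observations (see :func:`finite_difference_observations`) enter
  as additional, partially missing observation rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, PatientSeries
from .params import STATE_DIM, StateSpaceParams

_JITTER = 1e-10


class FilterError(RuntimeError):
    pass


@dataclass
class StateBelief:
    """Gaussian belief over the state at one visit."""

    mean: np.ndarray
    cov: np.ndarray
    index: int = 0
    kind: str = "updated"  # "predicted" | "updated"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError("belief covariance shape mismatch")


@dataclass
class FilteredSeries:
    """Filter output for one patient: updated and one-step-ahead beliefs."""

    patient_id: str
    visit_index: np.ndarray
    means: np.ndarray        # (J, n) updated means
    covs: np.ndarray         # (J, n, n) updated covariances
    pred_means: np.ndarray   # (J, n) predicted (prior) means
    pred_covs: np.ndarray    # (J, n, n)
    loglik: float


@dataclass
class SmoothedSeries:
    patient_id: str
    visit_index: np.ndarray
    means: np.ndarray        # (J, n) smoothed means
    covs: np.ndarray         # (J, n, n)
    lag_one: np.ndarray      # (J, n, n); lag_one[j] = Cov(a_j, a_{j-1} | all z)


def _sym(mat: np.ndarray) -> np.ndarray:
    return 0.5 * (mat + mat.T)


def kalman_predict(belief: StateBelief, params: StateSpaceParams) -> StateBelief:
    """One-step state extrapolation: mean' = T m, cov' = T P T' + Q."""
    if belief.mean.shape[0] != params.n:
        raise ValueError("belief dimension does not match parameters")
    mean = params.T @ belief.mean
    cov = _sym(params.T @ belief.cov @ params.T.T + params.Q)
    return StateBelief(mean=mean, cov=cov, index=belief.index + 1, kind="predicted")


def _masked_update(mean, cov, z, H, R):
    """Condition N(mean, cov) on the observed components of z = H a + v.

    Returns (mean', cov', loglik_increment).  NaN entries of z are
    treated as missing; with nothing observed the belief passes through.
    """
    obs = np.isfinite(np.asarray(z, dtype=float))
    if not obs.any():
        return mean, cov, 0.0
    Ho = H[obs]
    Ro = R[np.ix_(obs, obs)]
    zo = np.asarray(z, dtype=float)[obs]
    innov = zo - Ho @ mean
    S = _sym(Ho @ cov @ Ho.T + Ro)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        try:
            L = np.linalg.cholesky(S + _JITTER * np.eye(S.shape[0]))
        except np.linalg.LinAlgError:
            raise FilterError(
                "innovation covariance is numerically singular; "
                "consider regularizing R") from None
    # K = cov Ho' S^-1 via triangular solves
    PHt = cov @ Ho.T
    K = np.linalg.solve(L.T, np.linalg.solve(L, PHt.T)).T
    mean_new = mean + K @ innov
    IKH = np.eye(cov.shape[0]) - K @ Ho
    cov_new = _sym(IKH @ cov @ IKH.T + K @ Ro @ K.T)
    alpha = np.linalg.solve(L, innov)
    loglik = -0.5 * (obs.sum() * np.log(2.0 * np.pi)
                     + 2.0 * np.log(np.diag(L)).sum()
                     + alpha @ alpha)
    return mean_new, cov_new, float(loglik)


def kalman_update(belief: StateBelief, z, params: StateSpaceParams) -> StateBelief:
    """Condition a predicted belief on one (possibly partial) observation."""
    mean, cov, _ = _masked_update(belief.mean, belief.cov, z, params.H, params.R)
    return StateBelief(mean=mean, cov=cov, index=belief.index, kind="updated")


def _series_observations(series, params: StateSpaceParams) -> np.ndarray:
    if isinstance(series, PatientSeries):
        if params.m == len(series.observations[0]):
            return series.observations
        if params.m == params.n == STATE_DIM:
            return finite_difference_observations(series.observations,
                                                  series.visit_index)
        raise ValueError(
            f"cannot map 3-channel observations onto m={params.m} parameters")
    return np.asarray(series, dtype=float)


def filter_series(series, params: StateSpaceParams,
                  patient_id: str = "") -> FilteredSeries:
    """Run the forward predict/update recursion over one visit series.

    ``series`` may be a :class:`PatientSeries` or a raw (J, m) array with
    NaN for missing components.  The prior at the first visit is the
    population initial belief; each subsequent visit applies one predict
    step per unit of visit-index gap (missing visits are pure
    predictions) followed by a masked update.
    """
    if isinstance(series, PatientSeries):
        patient_id = patient_id or series.patient_id
        visit_index = series.visit_index
        Z = _series_observations(series, params)
    else:
        Z = np.asarray(series, dtype=float)
        visit_index = np.arange(len(Z))
    if len(Z) < 1:
        raise ValueError("series must contain at least one visit")
    if Z.shape[1] != params.m:
        raise ValueError(f"observations have {Z.shape[1]} channels, expected {params.m}")

    J, n = len(Z), params.n
    means = np.empty((J, n))
    covs = np.empty((J, n, n))
    pred_means = np.empty((J, n))
    pred_covs = np.empty((J, n, n))
    loglik = 0.0

    mean, cov = params.initial_mean, params.initial_cov
    for k in range(J):
        if k > 0:
            gap = int(visit_index[k] - visit_index[k - 1])
            for _ in range(gap):
                mean = params.T @ mean
                cov = _sym(params.T @ cov @ params.T.T + params.Q)
        pred_means[k] = mean
        pred_covs[k] = cov
        mean, cov, ll = _masked_update(mean, cov, Z[k], params.H, params.R)
        loglik += ll
        means[k] = mean
        covs[k] = cov
    return FilteredSeries(patient_id=patient_id, visit_index=np.asarray(visit_index),
                          means=means, covs=covs, pred_means=pred_means,
                          pred_covs=pred_covs, loglik=loglik)


def smooth_series(filtered: FilteredSeries, params: StateSpaceParams) -> SmoothedSeries:
    """Rauch-Tung-Striebel backward pass.

    Produces smoothed means/covariances and the lag-one covariances
    Cov(a_j, a_{j-1} | z_{0..J}) required by the EM M-step.  Assumes
    consecutive visit indices (the EM path filters contiguous series).
    """
    J, n = filtered.means.shape
    s_means = filtered.means.copy()
    s_covs = filtered.covs.copy()
    lag_one = np.zeros((J, n, n))
    for j in range(J - 2, -1, -1):
        Pp = filtered.pred_covs[j + 1]
        try:
            G = np.linalg.solve(Pp, params.T @ filtered.covs[j]).T
        except np.linalg.LinAlgError:
            G = filtered.covs[j] @ params.T.T @ np.linalg.pinv(Pp)
        s_means[j] = filtered.means[j] + G @ (s_means[j + 1] - filtered.pred_means[j + 1])
        s_covs[j] = _sym(filtered.covs[j] + G @ (s_covs[j + 1] - Pp) @ G.T)
        lag_one[j + 1] = s_covs[j + 1] @ G.T
    return SmoothedSeries(patient_id=filtered.patient_id,
                          visit_index=filtered.visit_index,
                          means=s_means, covs=s_covs, lag_one=lag_one)


def log_likelihood(cohort, params: StateSpaceParams) -> float:
    """Prediction-error-decomposition log-likelihood, additive over patients.

    ``cohort`` may be a :class:`~kfprog.cohort.Cohort` or an iterable of
    (J, m) observation arrays.  An empty cohort has log-likelihood 0.
    """
    total = 0.0
    for series in cohort:
        total += filter_series(series, params).loglik
    return total


def filter_cohort(cohort: Cohort, params: StateSpaceParams) -> dict[str, FilteredSeries]:
    """Filter every patient; keys are patient ids."""
    return {p.patient_id: filter_series(p, params) for p in cohort}


def finite_difference_observations(levels: np.ndarray,
                                   visit_index: np.ndarray | None = None) -> np.ndarray:
    """Expand (J, 3) level observations to (J, 9) pseudo-observations.

    Velocity at visit j is (x_j - x_{j-1}) / gap; acceleration is the
    difference of successive velocities divided by the gap.  The first
    visit's velocities and the first two visits' accelerations are NaN
    (masked) rather than fabricated zeros; differences across missing
    values propagate NaN.
    """
    levels = np.asarray(levels, dtype=float)
    J = len(levels)
    if visit_index is None:
        visit_index = np.arange(J)
    gaps = np.diff(np.asarray(visit_index, dtype=float))
    out = np.full((J, STATE_DIM), np.nan)
    vel = np.full((J, 3), np.nan)
    vel[1:] = (levels[1:] - levels[:-1]) / gaps[:, None]
    acc = np.full((J, 3), np.nan)
    acc[2:] = (vel[2:] - vel[1:-1]) / gaps[1:, None]
    for b in range(3):
        out[:, 3 * b] = levels[:, b]
        out[:, 3 * b + 1] = vel[:, b]
        out[:, 3 * b + 2] = acc[:, b]
    return out


def filtered_to_frame(filtered: dict[str, FilteredSeries]):
    """Long-format table of filtered state estimates and their variances."""
    import pandas as pd

    from .params import STATE_FIELDS

    rows = []
    for pid, fs in filtered.items():
        variances = np.diagonal(fs.covs, axis1=1, axis2=2)
        for k, j in enumerate(fs.visit_index):
            rows.append((pid, int(j), *fs.means[k], *variances[k]))
    cols = (["patient_id", "visit_index"]
            + [f"{f}_hat" for f in STATE_FIELDS]
            + [f"{f}_var" for f in STATE_FIELDS])
    return pd.DataFrame(rows, columns=cols)
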