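"""Generalized estimating equations for binary longitudinal responses.

Marginal logistic regression for clustered (per-patient) 0/1 outcomes:
logit link, Bernoulli variance v(mu) = mu(1 - mu), scale phi fixed at 1,
and an AR(1) working correlation Corr(y_s, y_t) = rho^|s-t| over
within-patient visit indices (actual index gaps are respected, so
missing visits widen the correlation lag).  Coefficients are obtained by
Fisher scoring on the estimating equations, alternated with a lag-1
moment update of rho; inference uses the robust (sandwich) covariance

    Cov(beta) = A^{-1} M A^{-1}

with A the model-based information and M the empirical outer product of
per-cluster scores.  Misspecifying the working correlation costs
efficiency, not consistency, which is why the sandwich is the default
covariance for Wald tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MAX_ABS_ETA = 35.0
_MAX_STEP = 5.0  # per-coordinate clamp on a scoring step (separation guard)


class GEEError(RuntimeError):
    pass


def logit_link(mu):
    """eta = log(mu / (1 - mu)); requires mu strictly inside (0, 1)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("logit link requires 0 < mu < 1")
    return np.log(mu / (1.0 - mu))


def inverse_logit(eta):
    """mu = 1 / (1 + exp(-eta)), clamped away from {0, 1} for stability."""
    eta = np.clip(np.asarray(eta, dtype=float), -MAX_ABS_ETA, MAX_ABS_ETA)
    return 1.0 / (1.0 + np.exp(-eta))


def bernoulli_variance(mu):
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("Bernoulli variance requires 0 < mu < 1")
    return mu * (1.0 - mu)


def working_correlation(times, rho: float) -> np.ndarray:
    """AR(1) working correlation rho^|s-t| over within-cluster visit indices."""
    if abs(rho) >= 1.0:
        raise ValueError("AR(1) parameter must satisfy |rho| < 1")
    t = np.asarray(times, dtype=float).reshape(-1)
    gaps = np.abs(t[:, None] - t[None, :])
    if rho == 0.0:
        return np.eye(len(t))
    return np.sign(rho) ** gaps * np.abs(rho) ** gaps if rho < 0 else rho ** gaps


def estimate_rho(pearson_residuals, clusters, times) -> float:
    """Lag-1 moment estimator of the AR(1) parameter.

    Averages products of Pearson residuals over within-cluster pairs of
    consecutive visits (index gap exactly 1), divided by the scale
    estimate (mean squared Pearson residual); clipped to (-0.99, 0.99).
    """
    e = np.asarray(pearson_residuals, dtype=float)
    clusters = np.asarray(clusters)
    times = np.asarray(times)
    codes = _stable_codes(clusters)
    order = np.lexsort((times, codes))
    e, codes, times = e[order], codes[order], times[order]
    adjacent = (np.diff(codes) == 0) & (np.diff(times) == 1)
    num = float(np.sum(e[:-1][adjacent] * e[1:][adjacent]))
    n_pairs = int(adjacent.sum())
    if n_pairs == 0:
        raise GEEError("no within-cluster consecutive-visit pairs for rho")
    scale = float(np.mean(e ** 2))
    if scale <= 0.0:
        raise GEEError("zero residual scale")
    return float(np.clip((num / n_pairs) / scale, -0.99, 0.99))


@dataclass
class RegressionData:
    """Design matrix, binary response and clustering for GEE.

    ``X`` includes the intercept column.  Rows must be sorted so that
    each cluster's observations are contiguous and time-ordered (the
    constructor sorts defensively).
    """

    X: np.ndarray
    y: np.ndarray
    cluster: np.ndarray
    time: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cluster = np.asarray(self.cluster)
        self.time = np.asarray(self.time, dtype=int)
        N = len(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != N or len(self.cluster) != N \
                or len(self.time) != N:
            raise ValueError("X, y, cluster, time must align")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("responses must be 0/1")
        if not self.names:
            self.names = [f"x{k}" for k in range(self.X.shape[1])]
        order = np.lexsort((self.time, _stable_codes(self.cluster)))
        self.X = self.X[order]
        self.y = self.y[order]
        self.cluster = self.cluster[order]
        self.time = self.time[order]
        for cid, sl in self._cluster_slices():
            if len(np.unique(self.time[sl])) != (sl.stop - sl.start):
                raise ValueError(f"duplicate times within cluster {cid}")

    def _cluster_slices(self):
        codes = _stable_codes(self.cluster)
        change = np.nonzero(np.diff(codes))[0] + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [len(codes)]))
        return [(self.cluster[a], slice(a, b)) for a, b in zip(starts, stops)]

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster))


def _stable_codes(cluster) -> np.ndarray:
    """Integer codes preserving first-appearance order (relabel-invariant fits)."""
    _, first_pos, inverse = np.unique(cluster, return_index=True, return_inverse=True)
    rank = np.argsort(np.argsort(first_pos))
    return rank[inverse]


@dataclass
class GEEFit:
    beta: np.ndarray
    rho: float
    robust_cov: np.ndarray
    naive_cov: np.ndarray
    n_clusters: int
    converged: bool
    iterations: int
    names: list[str] = field(default_factory=list)

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))


def _irls_init(X, y, n_steps: int = 5) -> np.ndarray:
    """A few IRLS steps of independence logistic regression for starting beta."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_steps):
        mu = inverse_logit(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        big = np.max(np.abs(step))
        if big > _MAX_STEP:
            step = step * (_MAX_STEP / big)
        beta = beta + step
    return beta


def gee_fit(data: RegressionData, corstr: str = "ar1",
            tol: float = 1e-8, max_iter: int = 100,
            fix_rho: float | None = None) -> GEEFit:
    """Fisher-scoring GEE fit.

    ``corstr`` is ``"ar1"`` or ``"independence"`` (the latter is AR(1)
    with rho fixed at 0).  ``fix_rho`` pins the working-correlation
    parameter (used for cross-implementation checks).  Non-convergence
    within ``max_iter`` returns a fit flagged ``converged=False``.
    """
    if corstr not in ("ar1", "independence"):
        raise ValueError(f"unknown correlation structure {corstr!r}")
    X, y = data.X, data.y
    N, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise GEEError("design matrix is rank deficient")
    slices = [sl for _, sl in data._cluster_slices()]
    gap_mats = [np.abs(data.time[sl][:, None] - data.time[sl][None, :]).astype(float)
                for sl in slices]

    if corstr == "independence":
        fix_rho = 0.0
    rho = 0.0 if fix_rho is None else float(fix_rho)
    beta = _irls_init(X, y)

    converged = False
    it = 0
    lhs = np.eye(p)
    scores = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = inverse_logit(eta)
        a = np.clip(mu * (1.0 - mu), 1e-10, None)
        sa = np.sqrt(a)
        resid = y - mu
        lhs = np.zeros((p, p))
        rhs = np.zeros(p)
        scores = []
        for sl, gaps in zip(slices, gap_mats):
            Xi = X[sl]
            Bi = Xi * a[sl][:, None]          # D_i = A_i X_i
            Vi = np.outer(sa[sl], sa[sl]) * (rho ** gaps if rho != 0.0
                                             else np.eye(len(gaps)))
            try:
                sol = np.linalg.solve(Vi, np.column_stack([Bi, resid[sl]]))
            except np.linalg.LinAlgError:
                Vi = Vi + 1e-10 * np.eye(len(gaps))
                sol = np.linalg.solve(Vi, np.column_stack([Bi, resid[sl]]))
            ViB, Vir = sol[:, :p], sol[:, p]
            lhs += Bi.T @ ViB
            g = Bi.T @ Vir
            rhs += g
            scores.append(g)
        try:
            step = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as exc:
            raise GEEError("singular information matrix") from exc
        big = np.max(np.abs(step))
        if big > _MAX_STEP:
            warnings.warn("large GEE step rescaled; possible separation",
                          RuntimeWarning, stacklevel=2)
            step = step * (_MAX_STEP / big)
        beta = beta + step

        d_rho = 0.0
        if fix_rho is None:
            mu_new = inverse_logit(X @ beta)
            e = (y - mu_new) / np.sqrt(np.clip(mu_new * (1.0 - mu_new), 1e-10, None))
            try:
                rho_new = estimate_rho(e, data.cluster, data.time)
            except GEEError:
                rho_new = rho  # no lag-1 pairs (e.g. singleton clusters)
            d_rho = abs(rho_new - rho)
            rho = rho_new
        if np.max(np.abs(step)) < tol and d_rho < 1e-6:
            converged = True
            break

    # sandwich at the final beta/rho (recompute scores at the solution)
    eta = X @ beta
    mu = inverse_logit(eta)
    a = np.clip(mu * (1.0 - mu), 1e-10, None)
    sa = np.sqrt(a)
    resid = y - mu
    lhs = np.zeros((p, p))
    M = np.zeros((p, p))
    for sl, gaps in zip(slices, gap_mats):
        Xi = X[sl]
        Bi = Xi * a[sl][:, None]
        Vi = np.outer(sa[sl], sa[sl]) * (rho ** gaps if rho != 0.0
                                         else np.eye(len(gaps)))
        sol = np.linalg.solve(Vi, np.column_stack([Bi, resid[sl]]))
        lhs += Bi.T @ sol[:, :p]
        g = Bi.T @ sol[:, p]
        M += np.outer(g, g)
    naive = np.linalg.inv(lhs)
    naive = 0.5 * (naive + naive.T)
    robust = naive @ M @ naive
    robust = 0.5 * (robust + robust.T)
    return GEEFit(beta=beta, rho=rho, robust_cov=robust, naive_cov=naive,
                  n_clusters=data.n_clusters, converged=converged,
                  iterations=it, names=list(data.names))


def predict_probability(fit: GEEFit, x) -> np.ndarray | float:
    """Marginal progression probability mu = expit(x' beta)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(fit.beta):
        raise ValueError(f"covariate length {x.shape[-1]} != {len(fit.beta)}")
    mu = inverse_logit(x @ fit.beta)
    return float(mu) if mu.ndim == 0 else mu


def wald_chisq(fit: GEEFit, index: int):
    """Robust Wald chi-square test of beta[index] = 0; returns (stat, p)."""
    var = fit.robust_cov[index, index]
    if var <= 0.0:
        raise GEEError(f"non-positive robust variance for coefficient {index}")
    stat = fit.beta[index] ** 2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))
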