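"""Parameter container for the linear-Gaussian biomarker state-space model.

The disease state of one eye is a 9-vector: level, velocity and acceleration
for each of the three monitored biomarkers — visual-field mean deviation
(MD, dB), pattern standard deviation (PSD, dB) and intraocular pressure
(IOP, mmHg).  State evolution is a linear stochastic difference equation

    alpha_j = T alpha_{j-1} + w_j,        w_j ~ N(0, Q)

and the clinic observes a linear projection with measurement noise

    z_j = H alpha_j + v_j,                v_j ~ N(0, R).

One visit step corresponds to roughly six months of follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

STATE_FIELDS = (
    "md", "md_vel", "md_acc",
    "psd", "psd_vel", "psd_acc",
    "iop", "iop_vel", "iop_acc",
)
BIOMARKERS = ("md", "psd", "iop")
STATE_DIM = len(STATE_FIELDS)

#: index of each biomarker's level component within the state vector
LEVEL_INDICES = {"md": 0, "psd": 3, "iop": 6}

_SCHEMA_VERSION = 1
_PSD_MIN_EIG = -1e-10


class ParameterError(ValueError):
    """Raised for dimensionally or numerically invalid state-space parameters."""


def _as_matrix(name: str, value, shape: tuple[int, int]) -> np.ndarray:
    arr = np.array(value, dtype=float)
    if arr.shape != shape:
        raise ParameterError(f"{name} must have shape {shape}, got {arr.shape}")
    return arr


def check_symmetric_psd(name: str, mat: np.ndarray, sym_tol: float = 1e-8,
                        min_eig: float = _PSD_MIN_EIG) -> None:
    """Require symmetry (to sym_tol) and eigenvalues >= min_eig."""
    if not np.allclose(mat, mat.T, atol=sym_tol, rtol=0.0):
        raise ParameterError(f"{name} must be symmetric")
    eigs = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    if eigs.min() < min_eig:
        raise ParameterError(
            f"{name} must be positive semidefinite (min eigenvalue {eigs.min():.3e})"
        )


@dataclass(frozen=True)
class StateSpaceParams:
    """Shared population parameters of the linear-Gaussian state-space model.

    Attributes
    ----------
    T : (n, n) transition matrix.
    Q : (n, n) process-noise covariance (symmetric PSD).
    H : (m, n) observation matrix, full row rank.
    R : (m, m) measurement-noise covariance (symmetric PSD).
    initial_mean : (n,) prior mean of the baseline state.
    initial_cov : (n, n) prior covariance of the baseline state.
    """

    T: np.ndarray
    Q: np.ndarray
    H: np.ndarray
    R: np.ndarray
    initial_mean: np.ndarray
    initial_cov: np.ndarray

    def __post_init__(self) -> None:
        T = np.array(self.T, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ParameterError(f"T must be square, got shape {T.shape}")
        n = T.shape[0]
        H = np.array(self.H, dtype=float)
        if H.ndim != 2 or H.shape[1] != n:
            raise ParameterError(f"H must have {n} columns, got shape {H.shape}")
        m = H.shape[0]
        Q = _as_matrix("Q", self.Q, (n, n))
        R = _as_matrix("R", self.R, (m, m))
        mu0 = np.array(self.initial_mean, dtype=float).reshape(-1)
        if mu0.shape != (n,):
            raise ParameterError(f"initial_mean must have length {n}")
        P0 = _as_matrix("initial_cov", self.initial_cov, (n, n))
        check_symmetric_psd("Q", Q)
        check_symmetric_psd("R", R)
        check_symmetric_psd("initial_cov", P0)
        if np.linalg.matrix_rank(H) < m:
            raise ParameterError("H must have full row rank")
        for field, value in (("T", T), ("Q", Q), ("H", H), ("R", R),
                             ("initial_mean", mu0), ("initial_cov", P0)):
            object.__setattr__(self, field, value)

    @property
    def n(self) -> int:
        """State dimension."""
        return self.T.shape[0]

    @property
    def m(self) -> int:
        """Observation dimension."""
        return self.H.shape[0]

    def replace(self, **kwargs) -> "StateSpaceParams":
        return _dc_replace(self, **kwargs)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "state_dim": self.n,
            "obs_dim": self.m,
            "T": self.T.tolist(),
            "Q": self.Q.tolist(),
            "H": self.H.tolist(),
            "R": self.R.tolist(),
            "initial_mean": self.initial_mean.tolist(),
            "initial_cov": self.initial_cov.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "StateSpaceParams":
        version = data.get("schema_version", _SCHEMA_VERSION)
        if version != _SCHEMA_VERSION:
            raise ParameterError(f"unsupported parameter schema version {version}")
        return cls(
            T=data["T"], Q=data["Q"], H=data["H"], R=data["R"],
            initial_mean=data["initial_mean"], initial_cov=data["initial_cov"],
        )

    @classmethod
    def from_json(cls, path) -> "StateSpaceParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def levels_observation_matrix(n: int = STATE_DIM) -> np.ndarray:
    """Observation matrix selecting the three biomarker levels (m = 3)."""
    H = np.zeros((len(BIOMARKERS), n))
    for row, name in enumerate(BIOMARKERS):
        H[row, LEVEL_INDICES[name]] = 1.0
    return H


def local_linear_trend_transition(acc_damping: float = 0.5) -> np.ndarray:
    """Structural 9x9 transition: level += velocity, velocity += acceleration,
    acceleration geometrically damped.

    Damping keeps long trajectories near-linear (glaucoma progresses slowly)
    while allowing curvature to enter through the acceleration channel.
    """
    block = np.array([[1.0, 1.0, 0.0],
                      [0.0, 1.0, 1.0],
                      [0.0, 0.0, float(acc_damping)]])
    T = np.zeros((STATE_DIM, STATE_DIM))
    for b in range(len(BIOMARKERS)):
        T[3 * b:3 * b + 3, 3 * b:3 * b + 3] = block
    return T
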