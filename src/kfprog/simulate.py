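"""Synthetic longitudinal glaucoma cohort generator.

Emulates the structure of a treated open-angle-glaucoma clinical-trial
population: visits approximately every six months, per-patient visit
counts drawn around a mean of 15.1 (SD 2.6) with at least four follow-up
exams, a progressing subpopulation whose MD declines steadily, and
random censoring standing in for treatment escalation
(trabeculectomy/ALT) or dropout.

Hidden 9-dimensional states evolve by the linear-Gaussian dynamics of
:mod:`kfprog.params`; the clinic observes the three biomarker levels
through Gaussian measurement noise.  Ground-truth states and parameters
are retained so that every downstream stage (filtering, EM, labeling,
regression, evaluation) can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .cohort import Cohort, PatientSeries
from .params import (
    STATE_DIM,
    LEVEL_INDICES,
    StateSpaceParams,
    levels_observation_matrix,
    local_linear_trend_transition,
)


@dataclass(frozen=True)
class DemographicsSpec:
    """Baseline demographic distributions (no effect on dynamics)."""

    age_mean: float = 58.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (35.0, 85.0)
    female_fraction: float = 0.45
    race_categories: tuple[str, ...] = ("white", "black", "other")
    race_probabilities: tuple[float, ...] = (0.55, 0.38, 0.07)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    Visit counts are drawn from round(N(visit_count_mean, visit_count_sd))
    truncated below at ``min_follow_ups + 1`` total visits.  The per-visit
    censoring hazard applies only once a patient has accrued the minimum
    follow-up count, so every emitted patient satisfies the inclusion
    criterion by construction.
    """

    n_patients: int = 500
    visit_count_mean: float = 15.1
    visit_count_sd: float = 2.6
    min_follow_ups: int = 4
    progressor_fraction: float = 0.25
    true_params: StateSpaceParams | None = None  # None -> default_sim_params()
    censor_hazard: float = 0.01
    #: additive offset on the initial MD velocity of progressors (dB/visit)
    progressor_md_velocity: float = -0.5
    progressor_md_velocity_sd: float = 0.15
    #: additive offset on the initial PSD velocity of progressors (dB/visit)
    progressor_psd_velocity: float = 0.15
    progressor_psd_velocity_sd: float = 0.05
    obs_missing_rate: float = 0.0
    demographics: DemographicsSpec = field(default_factory=DemographicsSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.progressor_fraction <= 1.0:
            raise ValueError("progressor_fraction must be in [0, 1]")
        if not 0.0 <= self.censor_hazard < 1.0:
            raise ValueError("censor_hazard must be in [0, 1)")
        if not 0.0 <= self.obs_missing_rate < 1.0:
            raise ValueError("obs_missing_rate must be in [0, 1)")

    def replace(self, **kwargs) -> "SimConfig":
        return _dc_replace(self, **kwargs)


def default_sim_params() -> StateSpaceParams:
    """Plausible population state-space parameters for a treated cohort.

    The numbers are stand-ins chosen to be clinically credible, not
    estimates from any trial: baseline MD around -5 dB (early-to-moderate
    field loss) with between-patient SD 4 dB, PSD around 4 dB, IOP around
    18 mmHg on therapy and drifting slowly downward; measurement-noise
    SDs of 1.5 dB (MD), 0.8 dB (PSD) and 2.5 mmHg (IOP) reflect typical
    test-retest variability.  Process noise is small relative to
    measurement noise, which is what makes filtering worthwhile.
    """
    T = local_linear_trend_transition(acc_damping=0.5)
    # per-biomarker process-noise variances: (level, velocity, acceleration)
    q_blocks = {
        "md": (0.04, 0.0025, 4e-4),
        "psd": (0.04, 0.0025, 4e-4),
        "iop": (0.25, 0.01, 2.5e-3),
    }
    Q = np.diag(np.concatenate([np.array(q_blocks[b]) for b in ("md", "psd", "iop")]))
    H = levels_observation_matrix()
    R = np.diag([1.5 ** 2, 0.8 ** 2, 2.5 ** 2])
    initial_mean = np.array([
        -5.0, 0.0, 0.0,     # MD level, velocity, acceleration
        4.0, 0.05, 0.0,     # PSD
        18.0, -0.1, 0.0,    # IOP (treated: slow decline)
    ])
    initial_cov = np.diag([
        16.0, 0.0025, 1e-4,
        4.0, 0.0025, 1e-4,
        9.0, 0.0025, 1e-4,
    ])
    return StateSpaceParams(T=T, Q=Q, H=H, R=R,
                            initial_mean=initial_mean, initial_cov=initial_cov)


def _draw_visit_count(rng: np.random.Generator, config: SimConfig) -> int:
    j = int(round(rng.normal(config.visit_count_mean, config.visit_count_sd)))
    return max(j, config.min_follow_ups + 1)


def _chol_psd(mat: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerating exact PSD (zero-variance) matrices."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        eigval, eigvec = np.linalg.eigh(0.5 * (mat + mat.T))
        eigval = np.clip(eigval, 0.0, None)
        return eigvec * np.sqrt(eigval)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a cohort from the generative state-space model.

    Deterministic given ``config`` (including its seed).  Returned
    patients carry both noisy observations and hidden true states.
    Progressors receive a negative initial MD-velocity offset (and a
    positive PSD-velocity offset); PSD observations are truncated at 0
    and IOP at a small positive floor at emission.
    """
    params = config.true_params if config.true_params is not None else default_sim_params()
    if params.n != STATE_DIM:
        raise ValueError(f"true_params must have state dimension {STATE_DIM}")
    rng = np.random.default_rng(config.seed)
    LQ = _chol_psd(params.Q)
    LR = _chol_psd(params.R)
    L0 = _chol_psd(params.initial_cov)
    demo = config.demographics

    patients: list[PatientSeries] = []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        n_visits = _draw_visit_count(rng, config)
        is_progressor = rng.random() < config.progressor_fraction

        alpha0 = params.initial_mean + L0 @ rng.standard_normal(params.n)
        if is_progressor:
            alpha0[LEVEL_INDICES["md"] + 1] += min(
                rng.normal(config.progressor_md_velocity,
                           config.progressor_md_velocity_sd), -0.1)
            alpha0[LEVEL_INDICES["psd"] + 1] += abs(
                rng.normal(config.progressor_psd_velocity,
                           config.progressor_psd_velocity_sd))

        states = np.empty((n_visits, params.n))
        states[0] = alpha0
        for j in range(1, n_visits):
            states[j] = params.T @ states[j - 1] + LQ @ rng.standard_normal(params.n)

        noise = rng.standard_normal((n_visits, params.m)) @ LR.T
        obs = states @ params.H.T + noise
        obs[:, 1] = np.maximum(obs[:, 1], 0.0)    # PSD >= 0
        obs[:, 2] = np.maximum(obs[:, 2], 0.5)    # IOP > 0
        if config.obs_missing_rate > 0.0:
            mask = rng.random(obs.shape) < config.obs_missing_rate
            mask[0, 0] = False  # keep baseline MD (needed for labeling)
            obs[mask] = np.nan

        # censoring: per-visit geometric hazard once past the minimum follow-up
        censored_at = None
        for j in range(config.min_follow_ups + 1, n_visits):
            if rng.random() < config.censor_hazard:
                censored_at = j
                break
        if censored_at is not None:
            states = states[:censored_at]
            obs = obs[:censored_at]
            n_visits = censored_at

        age = float(np.clip(rng.normal(demo.age_mean, demo.age_sd), *demo.age_range))
        sex = "female" if rng.random() < demo.female_fraction else "male"
        race = str(rng.choice(demo.race_categories, p=demo.race_probabilities))

        patients.append(PatientSeries(
            patient_id=f"P{i:0{width}d}",
            visit_index=np.arange(n_visits),
            observations=obs,
            age=age, sex=sex, race=race,
            censored_at=censored_at,
            true_states=states,
        ))
    return Cohort(patients, provenance=config)
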