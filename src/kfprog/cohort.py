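"""Longitudinal cohort containers and long-format CSV round-tripping.

A cohort is a set of patients, each with an ordered sequence of clinic
visits.  Visit ``j = 0`` is the baseline exam; subsequent visit indices
count roughly six-month follow-up intervals.  Each visit carries up to
three observed biomarkers (MD dB, PSD dB, IOP mmHg); individual
components may be missing (NaN).  Simulated cohorts additionally carry
the hidden ground-truth 9-dimensional state for every visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from .params import STATE_DIM, STATE_FIELDS

OBS_COLUMNS = ("md_db", "psd_db", "iop_mmhg")

COHORT_COLUMNS = (
    "patient_id", "visit_index", "md_db", "psd_db", "iop_mmhg",
    "age_baseline", "sex", "race", "censored",
)


class CohortFormatError(ValueError):
    """Raised when a cohort file violates the long-format schema."""


@dataclass
class PatientSeries:
    """One patient's ordered visit history.

    ``observations`` is (J, 3) with columns (MD, PSD, IOP); NaN marks a
    missing component.  ``censored_at`` is the first visit index at which
    the patient is no longer analyzable (treatment escalation / dropout);
    the inclusion filter drops any rows at or past it.  ``true_states``
    (simulation only) is (J, 9) aligned with ``visit_index``.
    """

    patient_id: str
    visit_index: np.ndarray
    observations: np.ndarray
    age: float
    sex: str
    race: str
    censored_at: int | None = None
    true_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.visit_index = np.asarray(self.visit_index, dtype=int)
        self.observations = np.asarray(self.observations, dtype=float)
        if self.observations.ndim != 2 or self.observations.shape[1] != len(OBS_COLUMNS):
            raise CohortFormatError(
                f"patient {self.patient_id}: observations must be (J, 3)")
        if len(self.visit_index) != len(self.observations):
            raise CohortFormatError(
                f"patient {self.patient_id}: visit_index and observations disagree")
        if np.any(np.diff(self.visit_index) <= 0):
            raise CohortFormatError(
                f"patient {self.patient_id}: visit indices must be strictly increasing")
        psd = self.observations[:, 1]
        iop = self.observations[:, 2]
        if np.nanmin(psd, initial=0.0) < 0:
            raise CohortFormatError(f"patient {self.patient_id}: PSD must be >= 0")
        if np.any(iop[np.isfinite(iop)] <= 0):
            raise CohortFormatError(f"patient {self.patient_id}: IOP must be > 0")
        if self.true_states is not None:
            self.true_states = np.asarray(self.true_states, dtype=float)
            if self.true_states.shape != (len(self.visit_index), STATE_DIM):
                raise CohortFormatError(
                    f"patient {self.patient_id}: true_states must be (J, {STATE_DIM})")

    @property
    def n_visits(self) -> int:
        return len(self.visit_index)

    @property
    def n_follow_ups(self) -> int:
        """Follow-up visits after the baseline exam."""
        return int(np.sum(self.visit_index > self.visit_index[0]))

    @property
    def md(self) -> np.ndarray:
        return self.observations[:, 0]

    @property
    def psd(self) -> np.ndarray:
        return self.observations[:, 1]

    @property
    def iop(self) -> np.ndarray:
        return self.observations[:, 2]

    def replace(self, **kwargs) -> "PatientSeries":
        return _dc_replace(self, **kwargs)


@dataclass
class Cohort:
    patients: list[PatientSeries]
    provenance: object = None

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise CohortFormatError("duplicate patient ids in cohort")

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def get(self, patient_id: str) -> PatientSeries:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def subset(self, patient_ids) -> "Cohort":
        wanted = set(patient_ids)
        return Cohort([p for p in self.patients if p.patient_id in wanted],
                      provenance=self.provenance)


def write_cohort(cohort: Cohort, path, truth_path=None) -> None:
    """Write a cohort as long-format CSV (one row per visit).

    The ``censored`` flag is 1 on the final row of a patient censored
    immediately after that visit.  Hidden states, when present, go to the
    separate ``truth_path`` CSV.
    """
    rows = []
    for p in cohort:
        for k, j in enumerate(p.visit_index):
            censored = int(
                p.censored_at is not None and k == p.n_visits - 1)
            rows.append((p.patient_id, int(j), p.observations[k, 0],
                         p.observations[k, 1], p.observations[k, 2],
                         p.age, p.sex, p.race, censored))
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.10g")
    if truth_path is not None:
        trows = []
        for p in cohort:
            if p.true_states is None:
                continue
            for k, j in enumerate(p.visit_index):
                trows.append((p.patient_id, int(j), *p.true_states[k]))
        tframe = pd.DataFrame(
            trows, columns=["patient_id", "visit_index", *STATE_FIELDS])
        tframe.to_csv(truth_path, index=False, float_format="%.10g")


def read_cohort(path, truth_path=None) -> Cohort:
    """Read a long-format cohort CSV (optionally with a truth CSV).

    Raises :class:`CohortFormatError` naming the offending row for
    non-monotone visit indices or duplicate (patient, visit) keys.
    Empty biomarker fields become NaN (masked), not errors.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"cohort file missing columns: {missing}")

    truth = None
    if truth_path is not None:
        truth = pd.read_csv(truth_path, dtype={"patient_id": str})
        truth = truth.set_index(["patient_id", "visit_index"])

    patients: list[PatientSeries] = []
    for pid, grp in frame.groupby("patient_id", sort=False):
        visits = grp["visit_index"].to_numpy()
        dup_mask = pd.Series(visits).duplicated().to_numpy()
        if dup_mask.any():
            pos = int(np.nonzero(dup_mask)[0][0])
            row = int(grp.index[pos]) + 2  # +2: header + 1-based
            raise CohortFormatError(
                f"row {row}: duplicate visit {visits[pos]} for patient {pid}")
        bad = np.nonzero(np.diff(visits) <= 0)[0]
        if bad.size:
            row = int(grp.index[bad[0] + 1]) + 2  # +2: header + 1-based
            raise CohortFormatError(
                f"row {row}: visit indices not increasing for patient {pid}")
        obs = grp[list(OBS_COLUMNS)].to_numpy(dtype=float)
        censored_flags = grp["censored"].to_numpy()
        censored_at = None
        if censored_flags[-1]:
            censored_at = int(visits[-1]) + 1
        true_states = None
        if truth is not None:
            try:
                true_states = np.vstack([
                    truth.loc[(pid, int(j)), list(STATE_FIELDS)].to_numpy(dtype=float)
                    for j in visits])
            except KeyError:
                true_states = None
        patients.append(PatientSeries(
            patient_id=str(pid), visit_index=visits, observations=obs,
            age=float(grp["age_baseline"].iloc[0]), sex=str(grp["sex"].iloc[0]),
            race=str(grp["race"].iloc[0]), censored_at=censored_at,
            true_states=true_states))
    return Cohort(patients, provenance=str(path))
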