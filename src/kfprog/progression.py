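"""Per-visit progression labels from MD trajectories.

A visit j >= 1 is labeled as significant progression when either

* the MD criterion fires: a loss of >= 3 dB relative to the baseline MD
  at visit j, *validated* by the same loss recurring at some later
  visit k > j (validation guards against one-off noise); or
* the HAP criterion fires: the visit's Hodapp-Anderson-Parrish severity
  stage is worse than at baseline (no future validation required).

The composite definition is the OR of the two; ``md_only`` and
``hap_only`` apply a single criterion.  The baseline visit is labeled 0
by definition.  Trajectories lacking a future visit cannot validate an
MD loss at the final visit, so tail visits that fire only the MD clause
are labeled 0 (they remain in the data, mirroring what a trial analysis
could observe).

HAP staging here is MD-threshold based (early > -6 dB; moderate
(-12, -6]; severe <= -12 dB, boundaries to the worse stage) because the
cohorts carry only summary indices, not individual field points.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientSeries

MD_LOSS_THRESHOLD_DB = 3.0
HAP_EARLY_FLOOR_DB = -6.0
HAP_MODERATE_FLOOR_DB = -12.0

DEFINITIONS = ("composite", "md_only", "hap_only")


class HapClass(IntEnum):
    EARLY = 0
    MODERATE = 1
    SEVERE = 2


def hap_class(md: float) -> HapClass:
    """MD-threshold HAP severity stage; boundaries go to the worse stage."""
    md = float(md)
    if not np.isfinite(md):
        raise ValueError(f"MD must be finite, got {md}")
    if md > HAP_EARLY_FLOOR_DB:
        return HapClass.EARLY
    if md > HAP_MODERATE_FLOOR_DB:
        return HapClass.MODERATE
    return HapClass.SEVERE


@dataclass
class ProgressionLabels:
    patient_id: str
    visit_index: np.ndarray
    labels: np.ndarray       # float: 0.0, 1.0, or NaN where MD was missing
    rationale: list[str]     # "none" | "md_validated" | "hap_shift" | "missing"
    definition: str

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.labels)


def label_md_trajectory(md, definition: str = "composite"):
    """Label one MD trajectory; returns (labels, rationale).

    ``md[0]`` is the baseline and must be finite; missing MD at a later
    visit yields a NaN label there (excluded from regression), and such
    visits cannot serve as validators either.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown definition {definition!r}")
    md = np.asarray(md, dtype=float)
    if len(md) < 2:
        raise ValueError("labeling needs at least 2 visits")
    if not np.isfinite(md[0]):
        raise ValueError("baseline MD is missing")
    baseline = md[0]
    loss = baseline - md
    finite = np.isfinite(md)
    fires = finite & (loss >= MD_LOSS_THRESHOLD_DB)
    # validated[j]: loss fires at j and at some finite k > j
    future_fire = np.zeros(len(md), dtype=bool)
    seen = False
    for k in range(len(md) - 1, 0, -1):
        future_fire[k] = seen
        seen = seen or fires[k]
    md_validated = fires & future_fire

    base_stage = hap_class(baseline)
    labels = np.zeros(len(md))
    rationale = ["none"] * len(md)
    for j in range(1, len(md)):
        if not finite[j]:
            labels[j] = np.nan
            rationale[j] = "missing"
            continue
        hap_shift = hap_class(md[j]) > base_stage
        if definition == "md_only":
            hit = md_validated[j]
        elif definition == "hap_only":
            hit = hap_shift
        else:
            hit = md_validated[j] or hap_shift
        if hit:
            labels[j] = 1.0
            rationale[j] = "md_validated" if md_validated[j] and definition != "hap_only" \
                else "hap_shift"
    return labels, rationale


def label_progression(series: PatientSeries, definition: str = "composite",
                      md_source: str = "raw", filtered=None) -> ProgressionLabels:
    """Label one patient from raw or Kalman-filtered MD.

    ``md_source="kalman"`` reads the MD level from the filtered state
    means (``filtered`` must be the patient's
    :class:`~kfprog.kalman.FilteredSeries`).
    """
    if md_source == "raw":
        md = series.md
    elif md_source == "kalman":
        if filtered is None:
            raise ValueError("md_source='kalman' requires a FilteredSeries")
        md = filtered.means[:, 0]
    else:
        raise ValueError(f"unknown md_source {md_source!r}")
    labels, rationale = label_md_trajectory(md, definition)
    return ProgressionLabels(patient_id=series.patient_id,
                             visit_index=series.visit_index.copy(),
                             labels=labels, rationale=rationale,
                             definition=definition)


def label_cohort(cohort: Cohort, definition: str = "composite",
                 md_source: str = "raw", filtered=None) -> dict[str, ProgressionLabels]:
    out = {}
    for p in cohort:
        f = None if filtered is None else filtered[p.patient_id]
        out[p.patient_id] = label_progression(p, definition, md_source, f)
    return out


def labels_to_frame(labels: dict[str, ProgressionLabels]) -> pd.DataFrame:
    rows = []
    for pid, lab in labels.items():
        for k, j in enumerate(lab.visit_index):
            val = "" if not np.isfinite(lab.labels[k]) else int(lab.labels[k])
            rows.append((pid, int(j), val, lab.rationale[k], lab.definition))
    return pd.DataFrame(rows, columns=["patient_id", "visit_index", "label",
                                       "rationale", "definition"])


def apply_inclusion_criteria(cohort: Cohort, min_follow_ups: int = 4):
    """Trial-style inclusion filter.

    Drops visits at/after each patient's censoring index, then drops
    patients left with fewer than ``min_follow_ups`` follow-up visits.
    Returns (filtered cohort, report) where the report counts removals
    per rule.
    """
    kept = []
    report = {
        "patients_in": len(cohort),
        "visits_in": sum(p.n_visits for p in cohort),
        "visits_dropped_censoring": 0,
        "patients_dropped_min_follow_ups": 0,
        "patients_out": 0,
        "visits_out": 0,
    }
    for p in cohort:
        if p.censored_at is not None:
            keep = p.visit_index < p.censored_at
            n_drop = int((~keep).sum())
            if n_drop:
                report["visits_dropped_censoring"] += n_drop
                p = PatientSeries(
                    patient_id=p.patient_id,
                    visit_index=p.visit_index[keep],
                    observations=p.observations[keep],
                    age=p.age, sex=p.sex, race=p.race,
                    censored_at=p.censored_at,
                    true_states=None if p.true_states is None else p.true_states[keep],
                )
        if p.n_follow_ups < min_follow_ups:
            report["patients_dropped_min_follow_ups"] += 1
            continue
        kept.append(p)
    report["patients_out"] = len(kept)
    report["visits_out"] = sum(p.n_visits for p in kept)
    return Cohort(kept, provenance=cohort.provenance), report
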