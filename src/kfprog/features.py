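"""Per-visit regression feature tables for the raw and Kalman arms.

Both arms expose the same nine dynamic features — level, velocity and
acceleration of MD, PSD and IOP — plus the baseline-referenced change in
MD and the demographic covariates.  The raw arm derives velocities and
accelerations by finite differences of the observed levels; the Kalman
arm reads all nine components off the filtered state means.  Change in
MD is MD_j - MD_0 computed within the chosen source (distinct from the
per-step velocity).

Finite-difference features exist only from visit 2 onward, so feature
tables are restricted to visits j >= 2 in both arms; this keeps the two
arms' row keys identical so both regressions see the same instances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .kalman import FilteredSeries, finite_difference_observations
from .progression import ProgressionLabels

DYNAMIC_FEATURES = (
    "md", "psd", "iop",
    "md_vel", "psd_vel", "iop_vel",
    "md_acc", "psd_acc", "iop_acc",
)
DEMOGRAPHIC_FEATURES = ("age", "sex_female", "race_black", "race_other")
FEATURE_COLUMNS = (*DYNAMIC_FEATURES, "delta_md", *DEMOGRAPHIC_FEATURES)

INITIAL_VARIABLES = ("md", "psd", "delta_md")
#: forward-selection candidate pool, in tie-break order
CANDIDATE_POOL = (
    "iop", "md_vel", "psd_vel", "iop_vel",
    "md_acc", "psd_acc", "iop_acc",
    "age", "sex_female", "race_black", "race_other",
)

MIN_FEATURE_VISIT = 2  # earliest visit with a defined acceleration


def assemble_features(cohort: Cohort, labels: dict[str, ProgressionLabels],
                      source: str = "raw",
                      filtered: dict[str, FilteredSeries] | None = None,
                      min_visit: int = MIN_FEATURE_VISIT):
    """Build the long-format feature table for one arm.

    Returns (table, n_dropped) where the table has one row per
    (patient, visit) with a defined label and complete features, and
    ``n_dropped`` counts eligible visits lost to missing features or
    labels.
    """
    if source not in ("raw", "kalman"):
        raise ValueError(f"unknown source {source!r}")
    rows = []
    n_dropped = 0
    for p in cohort:
        lab = labels[p.patient_id]
        if source == "kalman":
            if filtered is None or p.patient_id not in filtered:
                raise ValueError(
                    f"source='kalman' requires a FilteredSeries for {p.patient_id}")
            fs = filtered[p.patient_id]
            dyn = fs.means[:, [0, 3, 6, 1, 4, 7, 2, 5, 8]]  # levels, vels, accs
            delta_md = fs.means[:, 0] - fs.means[0, 0]
        else:
            expanded = finite_difference_observations(p.observations, p.visit_index)
            dyn = expanded[:, [0, 3, 6, 1, 4, 7, 2, 5, 8]]
            delta_md = p.observations[:, 0] - p.observations[0, 0]
        sex_female = 1.0 if p.sex == "female" else 0.0
        race_black = 1.0 if p.race == "black" else 0.0
        race_other = 1.0 if p.race == "other" else 0.0
        lab_by_visit = dict(zip(lab.visit_index, lab.labels))
        for k, j in enumerate(p.visit_index):
            if j < min_visit:
                continue
            y = lab_by_visit.get(int(j), np.nan)
            feats = (*dyn[k], delta_md[k], p.age, sex_female, race_black, race_other)
            if not np.isfinite(y) or not np.all(np.isfinite(feats)):
                n_dropped += 1
                continue
            rows.append((p.patient_id, int(j), *feats, float(y)))
    table = pd.DataFrame(
        rows, columns=["patient_id", "visit_index", *FEATURE_COLUMNS, "label"])
    table.attrs["source"] = source
    return table, n_dropped


def regression_data(table: pd.DataFrame, variables):
    """RegressionData with intercept from selected feature columns."""
    from .gee import RegressionData

    variables = list(variables)
    X = np.column_stack([np.ones(len(table))]
                        + [table[v].to_numpy(dtype=float) for v in variables])
    return RegressionData(
        X=X, y=table["label"].to_numpy(dtype=float),
        cluster=table["patient_id"].to_numpy(),
        time=table["visit_index"].to_numpy(dtype=int),
        names=["intercept", *variables])
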