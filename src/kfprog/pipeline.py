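"""End-to-end comparison of the Kalman-input and raw-input models.

``compare_models`` runs both arms on identical patient folds and
identical labels (computed from raw MD, so the two regressions share one
response) and reports averaged ROC curves, per-fold AUCs,
fitted-probability summaries by class, and specificity at fixed
sensitivities.  ``run_pipeline`` chains simulation, inclusion filtering,
labeling and the comparison; a single integer seed determines every
random draw, so repeated runs are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, write_cohort
from .em import em_fit
from .evaluation import (
    THRESHOLD_GRID,
    RocCurve,
    fitted_probability_summary,
    kfold_split_by_patient,
    pool_folds,
    specificity_at_sensitivity,
)
from .features import INITIAL_VARIABLES, assemble_features, regression_data
from .gee import gee_fit, predict_probability
from .kalman import filter_cohort, filter_series
from .params import (
    STATE_DIM,
    StateSpaceParams,
    levels_observation_matrix,
    local_linear_trend_transition,
)
from .progression import apply_inclusion_criteria, label_cohort
from .selection import forward_select
from .simulate import SimConfig, default_sim_params, simulate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the cross-validated model comparison.

    EM runs inside each training fold by default (fully out-of-sample
    Kalman arm); ``em_per_fold=False`` switches to a single whole-cohort
    EM fit, which is cheaper.  The EM iteration cap and tolerance here
    are the pipeline's working settings — looser than the library
    defaults because the CV loop refits the state-space model many
    times and the GEE arm is insensitive to late EM iterations.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    k_folds: int = 10
    definition: str = "composite"
    alpha: float = 0.10
    forward_selection: bool = True
    em_per_fold: bool = True
    em_estimate: tuple[str, ...] = ("Q", "R", "initial_mean", "initial_cov")
    em_max_iter: int = 15
    em_tol: float = 1e-4
    min_follow_ups: int = 4
    thresholds: np.ndarray = field(
        default_factory=lambda: THRESHOLD_GRID.copy())

    def replace(self, **kwargs) -> "PipelineConfig":
        return _dc_replace(self, **kwargs)


def generic_em_init(cohort: Cohort) -> StateSpaceParams:
    """Data-driven EM starting point that does not peek at the generator.

    Structural local-linear-trend transition; levels-only observation;
    R from half the variance of first differences of each observed
    channel (a crude split of short-horizon variability between process
    and measurement noise); baseline moments from the observed baseline
    visits.
    """
    obs = np.vstack([p.observations for p in cohort])
    first = np.vstack([p.observations[0] for p in cohort])
    diffs = np.vstack([np.diff(p.observations, axis=0) for p in cohort
                       if p.n_visits >= 2])
    r_diag = np.clip(0.5 * np.nanvar(diffs, axis=0), 1e-2, None)
    q_diag = np.tile([0.1, 0.01, 1e-3], 3)
    mu0 = np.zeros(STATE_DIM)
    p0_diag = np.tile([1.0, 0.25, 0.01], 3)
    for b, col in enumerate((0, 1, 2)):
        mu0[3 * b] = np.nanmean(first[:, col])
        p0_diag[3 * b] = max(np.nanvar(first[:, col]), 1e-2)
    return StateSpaceParams(
        T=local_linear_trend_transition(acc_damping=0.5),
        Q=np.diag(q_diag),
        H=levels_observation_matrix(),
        R=np.diag(r_diag),
        initial_mean=mu0,
        initial_cov=np.diag(p0_diag),
    )


def _fit_arm_fold(train: Cohort, test: Cohort, labels, arm: str,
                  config: PipelineConfig, em_params: StateSpaceParams | None):
    """Fit one arm on a training fold and score the test fold's visits."""
    filtered_train = filtered_test = None
    if arm == "kalman":
        if em_params is None:
            init = generic_em_init(train)
            em_params = em_fit(train, init, estimate=config.em_estimate,
                               tol=config.em_tol,
                               max_iter=config.em_max_iter).params
        filtered_train = filter_cohort(train, em_params)
        filtered_test = filter_cohort(test, em_params)
    table_train, _ = assemble_features(train, labels, source=arm,
                                       filtered=filtered_train)
    table_test, _ = assemble_features(test, labels, source=arm,
                                      filtered=filtered_test)
    if config.forward_selection:
        trace, fit = forward_select(table_train, alpha=config.alpha)
        variables = trace.final_variables
    else:
        variables = list(INITIAL_VARIABLES)
        fit = gee_fit(regression_data(table_train, variables))
        trace = None
    X_test = np.column_stack(
        [np.ones(len(table_test))]
        + [table_test[v].to_numpy(dtype=float) for v in variables])
    scores = predict_probability(fit, X_test)
    return scores, table_test["label"].to_numpy(dtype=float), fit, trace


def cross_validate(cohort: Cohort, labels, arm: str, k: int = 10,
                   seed: int = 0, config: PipelineConfig | None = None) -> RocCurve:
    """Patient-level k-fold cross-validation of one arm."""
    config = config or PipelineConfig()
    folds = kfold_split_by_patient(cohort.patient_ids, k=k, seed=seed)
    return _run_arm(cohort, labels, folds, arm, config)


def _run_arm(cohort: Cohort, labels, folds, arm: str,
             config: PipelineConfig) -> RocCurve:
    em_params = None
    if arm == "kalman" and not config.em_per_fold:
        init = generic_em_init(cohort)
        em_params = em_fit(cohort, init, estimate=config.em_estimate,
                           tol=config.em_tol,
                           max_iter=config.em_max_iter).params
    fold_scores, fold_labels = [], []
    for fold_ids in folds:
        test = cohort.subset(fold_ids)
        train = cohort.subset([pid for pid in cohort.patient_ids
                               if pid not in set(fold_ids)])
        scores, y, _, _ = _fit_arm_fold(train, test, labels, arm, config,
                                        em_params)
        fold_scores.append(scores)
        fold_labels.append(y)
    return pool_folds(fold_scores, fold_labels, config.thresholds)


@dataclass
class ComparisonReport:
    kalman: RocCurve
    raw: RocCurve
    kalman_fitted: dict
    raw_fitted: dict
    specificity_at: dict
    n_patients: int
    n_instances: int

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_instances": self.n_instances,
            "kalman": {"roc": self.kalman.to_dict(),
                       "fitted_probabilities": self.kalman_fitted},
            "raw": {"roc": self.raw.to_dict(),
                    "fitted_probabilities": self.raw_fitted},
            "specificity_at_sensitivity": self.specificity_at,
        }


def compare_models(cohort: Cohort, config: PipelineConfig | None = None,
                   seed: int = 0) -> ComparisonReport:
    """Evaluate both arms on identical folds and identical (raw-MD) labels."""
    config = config or PipelineConfig()
    labels = label_cohort(cohort, definition=config.definition, md_source="raw")
    folds = kfold_split_by_patient(cohort.patient_ids, k=config.k_folds, seed=seed)
    kalman_curve = _run_arm(cohort, labels, folds, "kalman", config)
    raw_curve = _run_arm(cohort, labels, folds, "raw", config)
    spec_at = {}
    for target in (0.90, 0.95):
        key = f"sensitivity_{target:.2f}"
        spec_at[key] = {
            "kalman": specificity_at_sensitivity(
                kalman_curve.mean_sensitivity, kalman_curve.mean_specificity, target),
            "raw": specificity_at_sensitivity(
                raw_curve.mean_sensitivity, raw_curve.mean_specificity, target),
        }
    return ComparisonReport(
        kalman=kalman_curve, raw=raw_curve,
        kalman_fitted=fitted_probability_summary(kalman_curve.scores,
                                                 kalman_curve.labels),
        raw_fitted=fitted_probability_summary(raw_curve.scores, raw_curve.labels),
        specificity_at=spec_at,
        n_patients=len(cohort),
        n_instances=int(len(kalman_curve.labels)),
    )


def md_denoising_mse(cohort: Cohort, params: StateSpaceParams | None = None) -> dict:
    """MSE of raw vs Kalman-filtered MD against the true MD level.

    Requires a simulated cohort (true states present).  Filtering uses
    the supplied parameters (default: the generator's own), i.e. this
    measures the filter's noise reduction under a correct model.
    """
    params = params or default_sim_params()
    raw_sq, kal_sq, n = 0.0, 0.0, 0
    for p in cohort:
        if p.true_states is None:
            raise ValueError("denoising MSE needs ground-truth states")
        fs = filter_series(p, params)
        truth = p.true_states[:, 0]
        obs = p.observations[:, 0]
        mask = np.isfinite(obs)
        raw_sq += float(np.sum((obs[mask] - truth[mask]) ** 2))
        kal_sq += float(np.sum((fs.means[mask, 0] - truth[mask]) ** 2))
        n += int(mask.sum())
    return {"md_mse_raw": raw_sq / n, "md_mse_kalman": kal_sq / n, "n_visits": n}


def run_pipeline(seed: int, config: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Simulate, filter, label and evaluate; optionally write the report.

    The single ``seed`` drives both the cohort draw and the fold
    assignment through independent spawned streams.
    """
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    sim_seed, cv_seed = (int(child.generate_state(1)[0] % (2 ** 31))
                         for child in ss.spawn(2))
    cohort = simulate_cohort(config.sim.replace(seed=sim_seed))
    included, inclusion_report = apply_inclusion_criteria(
        cohort, min_follow_ups=config.min_follow_ups)
    report = compare_models(included, config, seed=cv_seed)
    denoise = md_denoising_mse(included,
                               config.sim.true_params or default_sim_params())
    visit_counts = [p.n_visits for p in included]
    labels = label_cohort(included, definition=config.definition)
    label_values = np.concatenate([lab.labels for lab in labels.values()])
    out = {
        "seed": seed,
        "inclusion": inclusion_report,
        "mean_visit_count": float(np.mean(visit_counts)),
        "sd_visit_count": float(np.std(visit_counts, ddof=1)),
        "progression_prevalence": float(np.nanmean(label_values)),
        "n_labeled_visits": int(np.isfinite(label_values).sum()),
        "denoising": denoise,
        "comparison": report.to_dict(),
    }
    if out_dir is not None:
        _write_report(out, report, included, Path(out_dir))
    return out


def _write_report(out: dict, report: ComparisonReport, cohort: Cohort,
                  out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(out, fh, indent=2)
    write_cohort(cohort, out_dir / "cohort.csv", out_dir / "cohort_truth.csv")
    roc_rows = pd.DataFrame({
        "threshold": report.kalman.thresholds,
        "kalman_sensitivity": report.kalman.mean_sensitivity,
        "kalman_specificity": report.kalman.mean_specificity,
        "raw_sensitivity": report.raw.mean_sensitivity,
        "raw_specificity": report.raw.mean_specificity,
    })
    roc_rows.to_csv(out_dir / "mean_roc.csv", index=False)
    n_folds = max(len(report.kalman.fold_aucs), len(report.raw.fold_aucs))
    pad = lambda xs: list(xs) + [np.nan] * (n_folds - len(xs))
    pd.DataFrame({
        "fold": np.arange(n_folds),
        "kalman_auc": pad(report.kalman.fold_aucs),
        "raw_auc": pad(report.raw.fold_aucs),
    }).to_csv(out_dir / "fold_aucs.csv", index=False)
    plot_roc(report, out_dir / "roc_curves.png")


def plot_roc(report: ComparisonReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for curve, label, style in ((report.kalman, "Kalman filter estimates", "-"),
                                (report.raw, "Raw observations", "--")):
        ax.plot(1.0 - curve.mean_specificity, curve.mean_sensitivity, style,
                label=f"{label} (mean AUC {curve.auc_mean:.3f})")
    ax.plot([0, 1], [0, 1], ":", color="grey", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title("Cross-validated mean ROC")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
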