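"""Patient-level cross-validated ROC evaluation of the two model arms.

Folds partition patients (never visits — within-patient correlation
would otherwise leak across the train/test boundary).  For each fold the
training patients alone drive every fitted component: EM state-space
estimation (Kalman arm), forward variable selection and the GEE fit.
Test-fold visits are scored with the trained model; sensitivities and
specificities on a fixed threshold grid are averaged across folds, and
an empirical-ROC trapezoidal AUC is computed per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

THRESHOLD_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


class EvaluationError(ValueError):
    pass


def kfold_split_by_patient(patient_ids, k: int = 10, seed: int = 0) -> list[list[str]]:
    """Partition patients into k near-equal folds, deterministically per seed."""
    ids = list(patient_ids)
    if len(ids) < k:
        raise EvaluationError(f"need at least k={k} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(order, k)]


def roc_points(scores, labels, thresholds=THRESHOLD_GRID):
    """(sensitivity, specificity) at each threshold; predict 1 iff score >= t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires both classes present")
    thresholds = np.asarray(thresholds, dtype=float)
    pred = scores[None, :] >= thresholds[:, None]
    sensitivity = (pred & pos).sum(axis=1) / n_pos
    specificity = (~pred & neg).sum(axis=1) / n_neg
    return sensitivity, specificity


def auc_trapezoid(scores, labels) -> float:
    """Trapezoidal area under the empirical ROC.

    Thresholds run over the distinct scores, so ties contribute diagonal
    segments and the result equals the Mann-Whitney concordance
    probability with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group tied scores into single threshold steps
    boundary = np.nonzero(np.diff(s))[0]
    stops = np.concatenate((boundary + 1, [len(s)]))
    tp = np.concatenate(([0.0], np.cumsum(y)[stops - 1]))
    fp = np.concatenate(([0.0], np.cumsum(1.0 - y)[stops - 1]))
    tpr = tp / n_pos
    fpr = fp / n_neg
    return float(np.trapezoid(tpr, fpr))


def specificity_at_sensitivity(sensitivity, specificity, target: float) -> float:
    """Specificity where the mean ROC attains the target sensitivity.

    Linear interpolation between adjacent threshold-grid points;
    sensitivity is non-increasing along the grid.
    """
    sens = np.asarray(sensitivity, dtype=float)
    spec = np.asarray(specificity, dtype=float)
    # traverse in increasing-sensitivity order
    s = sens[::-1]
    sp = spec[::-1]
    if target <= s[0]:
        return float(sp[0])
    if target >= s[-1]:
        return float(sp[-1])
    idx = int(np.searchsorted(s, target))
    s0, s1 = s[idx - 1], s[idx]
    if s1 == s0:
        return float(sp[idx])
    w = (target - s0) / (s1 - s0)
    return float(sp[idx - 1] + w * (sp[idx] - sp[idx - 1]))


@dataclass
class RocCurve:
    thresholds: np.ndarray
    mean_sensitivity: np.ndarray
    mean_specificity: np.ndarray
    fold_aucs: list[float]
    auc_mean: float
    auc_variance: float
    #: pooled out-of-fold scores and labels (for fitted-probability summaries)
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    labels: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "mean_sensitivity": self.mean_sensitivity.tolist(),
            "mean_specificity": self.mean_specificity.tolist(),
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "auc_mean": float(self.auc_mean),
            "auc_variance": float(self.auc_variance),
        }


def pool_folds(fold_scores, fold_labels, thresholds=THRESHOLD_GRID) -> RocCurve:
    """Average per-fold ROC points on the shared grid; per-fold AUCs.

    Folds whose test labels contain a single class are excluded from the
    averages with a warning (their AUC is undefined).
    """
    sens_rows, spec_rows, aucs = [], [], []
    all_scores, all_labels = [], []
    for scores, labels in zip(fold_scores, fold_labels):
        all_scores.append(np.asarray(scores, dtype=float))
        all_labels.append(np.asarray(labels, dtype=float))
        try:
            sens, spec = roc_points(scores, labels, thresholds)
        except EvaluationError:
            warnings.warn("fold with single-class test labels excluded from ROC",
                          RuntimeWarning, stacklevel=2)
            continue
        sens_rows.append(sens)
        spec_rows.append(spec)
        aucs.append(auc_trapezoid(scores, labels))
    if not aucs:
        raise EvaluationError("no fold had both classes in its test labels")
    aucs_arr = np.asarray(aucs)
    variance = float(np.var(aucs_arr, ddof=1)) if len(aucs) > 1 else 0.0
    return RocCurve(
        thresholds=np.asarray(thresholds, dtype=float),
        mean_sensitivity=np.mean(sens_rows, axis=0),
        mean_specificity=np.mean(spec_rows, axis=0),
        fold_aucs=aucs, auc_mean=float(aucs_arr.mean()), auc_variance=variance,
        scores=np.concatenate(all_scores), labels=np.concatenate(all_labels))


def fitted_probability_summary(scores, labels) -> dict:
    """Class-wise mean (SD) of fitted probabilities and a normal 95% CI
    for the progressing-minus-nonprogressing difference in means."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    prog = scores[labels == 1]
    nonprog = scores[labels == 0]
    diff = prog.mean() - nonprog.mean()
    se = float(np.sqrt(prog.var(ddof=1) / len(prog)
                       + nonprog.var(ddof=1) / len(nonprog)))
    return {
        "progressing_mean": float(prog.mean()),
        "progressing_sd": float(prog.std(ddof=1)),
        "nonprogressing_mean": float(nonprog.mean()),
        "nonprogressing_sd": float(nonprog.std(ddof=1)),
        "difference": float(diff),
        "difference_ci95": [float(diff - 1.959963984540054 * se),
                            float(diff + 1.959963984540054 * se)],
        "n_progressing": int(len(prog)),
        "n_nonprogressing": int(len(nonprog)),
    }
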