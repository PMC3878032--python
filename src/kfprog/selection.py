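"""Forward variable selection for the progression GEE model.

Selection starts from {intercept, MD, PSD, change-in-MD}.  Each round
fits the current model augmented with every remaining candidate, takes
the candidate's robust Wald chi-square p-value, and adds the candidate
with the smallest p-value if it is below alpha (default 0.10); ties are
broken by candidate-pool order, so the procedure is deterministic given
the data.  Candidates whose augmented fit fails to converge are skipped
for that round with a logged warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .features import CANDIDATE_POOL, INITIAL_VARIABLES, regression_data
from .gee import GEEFit, gee_fit, wald_chisq


@dataclass
class SelectionTrace:
    added: list[tuple[str, float]] = field(default_factory=list)
    final_variables: list[str] = field(default_factory=list)
    stopping_reason: str = ""

    def to_dict(self) -> dict:
        return {"added": [{"variable": v, "p_value": p} for v, p in self.added],
                "final_variables": list(self.final_variables),
                "stopping_reason": self.stopping_reason}


def forward_select(table: pd.DataFrame, alpha: float = 0.10,
                   corstr: str = "ar1",
                   initial=INITIAL_VARIABLES, candidates=CANDIDATE_POOL,
                   tol: float = 1e-8, max_iter: int = 100):
    """Run forward selection; returns (SelectionTrace, final GEEFit)."""
    selected = list(initial)
    remaining = [c for c in candidates if c not in selected]
    trace = SelectionTrace()
    while True:
        if not remaining:
            trace.stopping_reason = "candidate pool exhausted"
            break
        best: tuple[float, int, str] | None = None
        for pos, cand in enumerate(remaining):
            data = regression_data(table, selected + [cand])
            try:
                fit = gee_fit(data, corstr=corstr, tol=tol, max_iter=max_iter)
            except Exception as exc:  # rank deficiency etc.
                warnings.warn(f"candidate {cand!r} skipped: {exc}",
                              RuntimeWarning, stacklevel=2)
                continue
            if not fit.converged:
                warnings.warn(f"candidate {cand!r} skipped: non-convergent fit",
                              RuntimeWarning, stacklevel=2)
                continue
            _, p_value = wald_chisq(fit, len(selected) + 1)  # +1: intercept
            if best is None or p_value < best[0]:
                best = (p_value, pos, cand)
        if best is None:
            trace.stopping_reason = "no convergent candidate fits"
            break
        p_value, _, cand = best
        if p_value >= alpha:
            trace.stopping_reason = f"smallest p-value {p_value:.4g} >= alpha {alpha}"
            break
        trace.added.append((cand, p_value))
        selected.append(cand)
        remaining.remove(cand)
    trace.final_variables = list(selected)
    final_fit = gee_fit(regression_data(table, selected), corstr=corstr,
                        tol=tol, max_iter=max_iter)
    return trace, final_fit


def fit_report(fit: GEEFit, trace: SelectionTrace | None = None) -> dict:
    """JSON-ready summary: coefficients, robust SEs, odds ratios, rho."""
    report = {
        "coefficients": {
            name: {"beta": float(b), "robust_se": float(se),
                   "odds_ratio": float(orat)}
            for name, b, se, orat in zip(fit.names, fit.beta, fit.robust_se,
                                         fit.odds_ratios())
        },
        "rho": float(fit.rho),
        "n_clusters": int(fit.n_clusters),
        "converged": bool(fit.converged),
        "iterations": int(fit.iterations),
    }
    if trace is not None:
        report["selection"] = trace.to_dict()
    return report
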