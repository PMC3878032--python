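# Methods

`kfprog` implements a noise-aware pipeline for identifying significant
open-angle-glaucoma (OAG) progression from longitudinal clinic data:
Kalman-filter state estimation of visual-field and pressure biomarkers,
a clinically motivated per-visit progression label, marginal logistic
regression by generalized estimating equations (GEE), and a
cross-validated ROC comparison of the model built on filtered state
estimates against the same model built on raw measurements.  Because no
suitable clinical-trial dataset is publicly available, a synthetic
cohort generator with known ground truth stands in for the data and
makes every stage testable end to end.

## State-space model

The disease state of patient *i* at visit *j* is
α<sub>ij</sub> ∈ ℝ⁹: level, velocity and acceleration of mean deviation
(MD, dB), pattern standard deviation (PSD, dB) and intraocular pressure
(IOP, mmHg).  One visit step is ≈ 6 months.  Dynamics and observation
are linear-Gaussian:

    α_ij = T α_ij−1 + w_ij,   w ~ N(0, Q)
    z_ij = H α_ij + v_ij,     v ~ N(0, R)

`T` is block-diagonal with one 3×3 local-linear-trend block per
biomarker: level += velocity, velocity += acceleration, acceleration
damped by 0.5 per step.  The damping keeps long trajectories
near-linear, which suits a slowly progressing disease, while letting
curvature enter transiently.

Two observation conventions are supported.  The pipeline's default
observes the three measured levels (`H` selects MD/PSD/IOP; m = 3) and
lets the filter infer velocities and accelerations as latent state.
The alternative (`finite_difference_observations`) feeds
finite-differenced velocity/acceleration pseudo-observations through an
identity `H` (m = 9) with the leading undefined entries masked.  We
default to m = 3 because the differenced pseudo-observations carry
errors that are correlated across channels and visits, which a
diagonal-R model misstates, and because the filter recovers the same
nine state components either way at a third of the cost.

### Filtering, smoothing, likelihood

`filter_series` runs the standard predict/update recursion with
Joseph-form covariance updates (symmetric PSD by construction), masked
handling of missing observation components, and pure prediction across
missing visits.  `smooth_series` is the Rauch-Tung-Striebel backward
pass, also producing the lag-one covariances Cov(α_j, α_j−1 | all z)
needed by EM.  The log-likelihood is the Gaussian prediction-error
decomposition accumulated by the filter.  Correctness is pinned by
tests against a joint-Gaussian oracle that stacks all states and
observations of a short series and conditions directly (agreement to
1e−8 on systems up to 3 state dimensions and 4 visits).

### EM estimation

`em_fit` pools filter/smoother sufficient statistics across patients
(parameters are population-shared; personalization enters only through
per-patient filtering) and applies closed-form M-step updates for a
chosen subset of {T, Q, R, initial_mean, initial_cov}.  By default `T`
stays fixed at its structural form: an unrestricted 9×9 transition is
weakly identified at realistic cohort sizes.  With partially missing
observations the R update is restricted to its diagonal.  Convergence:
relative log-likelihood change < 1e−6, cap 200 iterations; the trace is
monitored and a decrease beyond 1e−8 (relative) raises an error, since
exact EM cannot descend.  When some components are missing, negligible
negative eigenvalues from round-off are clipped to keep Q, R, Σ₀ PSD.

## Progression labeling

Visit *j* ≥ 1 is labeled progressed when (a) MD has dropped ≥ 3 dB from
the baseline visit AND the same loss recurs at some later visit *k* > *j*
(validation against one-off noise), or (b) the visit's severity stage
under a Hodapp-Anderson-Parrish-style staging is worse than baseline
(no validation needed).  `composite` is the OR; `md_only` / `hap_only`
apply one clause.  Staging is MD-threshold based — early > −6 dB,
moderate (−12, −6], severe ≤ −12 dB, boundaries to the worse stage —
because the cohort carries summary indices, not individual field
points; full HAP criteria also use point-level defect clusters, so this
is a deliberate approximation (see Limitations).  Visits whose MD loss
fires but that have no later visit to validate it are labeled 0 and
kept.  The labeler is verified against a literal (j, k) double-loop
checker on random trajectories.

Inclusion mirrors a trial analysis: visits at/after censoring
(treatment escalation or dropout) are removed, then patients with
fewer than 4 remaining follow-up visits are excluded, with a report of
counts removed per rule.

## GEE logistic regression

The marginal model is logit(μ_ij) = x_ijᵀβ with Bernoulli variance
μ(1−μ), scale φ = 1, and an AR(1) working correlation
Corr(y_is, y_it) = ρ^|s−t| over visit indices (index gaps from missing
visits widen the lag).  β is obtained by Fisher scoring of the
estimating equations, alternated with a lag-1 moment update of ρ
(mean product of adjacent-visit Pearson residuals over the mean squared
residual, clipped to ±0.99).  Initialization: five IRLS steps of
independence logistic regression; convergence max|Δβ| < 1e−8 within
100 iterations; steps larger than 5 are rescaled (direction preserved)
as a separation guard.  Inference uses the robust sandwich covariance
A⁻¹MA⁻¹; Wald χ²(1) tests use robust variances.  Tests check the
degenerate reductions (singleton clusters = ordinary logistic MLE;
independence = AR(1) with ρ pinned at 0), the estimating-function
residual at convergence, coverage of robust intervals under a
latent-threshold AR(1) generator, and agreement with an established
GEE implementation on a fixed dataset.

## Feature tables and model building

Both arms expose the same covariates per visit: the nine dynamic
components, change-in-MD from baseline (distinct from the per-step
velocity), age at baseline, sex, and race indicators.  The raw arm
derives velocity/acceleration by finite differences; the Kalman arm
reads all nine from the filtered means, with change-in-MD computed
within its own source.  Finite differences are undefined before visit
2, so both arms are restricted to visits j ≥ 2 — this also guarantees
the two arms score exactly the same instances.

Forward selection starts from {intercept, MD, PSD, ΔMD}; each round
adds the candidate with the smallest robust Wald χ² p-value if it is
below α = 0.10, with ties broken by the documented candidate order and
non-convergent candidate fits skipped with a warning.

## Evaluation protocol

Folds partition patients (never visits; within-patient correlation
would leak otherwise).  Within each training fold, and before seeing
any test patient: EM state-space estimation from a data-driven starting
point (levels-only observation; R initialized at half the variance of
first differences), filtering, feature assembly, forward selection and
the GEE fit.  Test-fold visits are scored by the fitted marginal
probability.  Sensitivity/specificity are computed on a fixed threshold
grid (0 to 1, step 0.01; predict 1 iff score ≥ t) and averaged across
folds; AUC is the trapezoidal area of each fold's empirical ROC (equal
to Mann-Whitney concordance with ties at ½), reported as mean and
sample variance over folds.  Specificity at fixed sensitivity (0.90,
0.95) is linearly interpolated on the mean curve.  Labels always come
from raw MD so both arms share one response.  A single integer seed
drives the cohort draw and fold assignment through spawned streams;
the whole pipeline is bit-reproducible.

Working sizes: the default comparison uses 500 simulated patients,
10-fold patient CV, and per-fold EM capped at 15 iterations with
tolerance 1e−4 (the GEE arm is insensitive to late EM iterations; a
whole-cohort single EM fit is available via `em_per_fold=False`).

## Synthetic cohort

The generator emulates a treated early-to-moderate OAG trial
population.  Per-patient visit counts are round(N(15.1, 2.6²)),
truncated so every patient has at least 4 follow-ups; a geometric
per-visit censoring hazard (0.01) applies only after the minimum
follow-up count, standing in for treatment escalation.  Baseline
states: MD ~ N(−5, 4²) dB, PSD ~ 4 dB, IOP ~ N(18, 3²) mmHg declining
slowly under therapy.  A progressor subpopulation (fraction 0.25)
receives a negative initial MD-velocity offset ~ N(−0.5, 0.15²)
dB/visit (≈ −1 dB/year) and a small upward PSD-velocity offset, keeping
the generative law inside the linear-Gaussian family so parameter
recovery stays well-posed.  Measurement-noise SDs are 1.5 dB (MD),
0.8 dB (PSD) and 2.5 mmHg (IOP) — typical test-retest variability —
with process noise much smaller, which is precisely the regime where
filtering pays off (filtered MD is ≈ 2.3× closer to truth in MSE than
the raw measurements).  PSD is truncated at 0 and IOP floored at
emission.  Demographics are drawn but carry no effect on dynamics.

What the generator does **not** emulate: individual visual-field test
points, calendar-date scheduling, treatment response, state-dependent
censoring, and non-Gaussian (heavy-tailed) measurement error.  Passing
tests therefore demonstrate correctness of the machinery and behavior
under the linear-Gaussian idealization, not performance on clinical
data.

## Known limitations

* **The two-arm comparison favors the raw arm by construction.**  The
  progression label is computed from the raw MD trajectory: the ≥ 3 dB
  clause and the MD-threshold stage shift are read directly off raw
  features, and with Gaussian noise the depth of an MD loss is
  monotonically predictive of its own future validation.  The raw
  model's change-in-MD covariate is therefore a near-sufficient
  statistic for the label, and a score computed from the *hidden true
  state* — the ceiling for any filtered-state model — ranks labels
  worse than raw change-in-MD alone.  Consequently the Kalman arm's
  cross-validated AUC sits a few points below the raw arm's on this
  synthetic cohort at every noise level we examined, and the
  corresponding directional end-to-end test fails by design of the
  synthetic labeling, not through an estimation defect.  In clinical
  data the situation differs in two ways this generator cannot
  represent: severity staging uses individual field points (not a
  function of either arm's features), and visual-field noise is
  heavy-tailed (a single unreliable test fires deep losses whose depth
  does not predict validation).  Both break the raw arm's mechanical
  link to the label.
* MD-threshold staging is a coarse stand-in for point-level HAP
  criteria; a point-level hook can replace `hap_class` when point data
  exist.
* Fixed unit visit spacing; no continuous-time transition for irregular
  gaps (missing visits are handled by extra prediction steps).
* Under partial missingness EM updates only the diagonal of R.
* ρ is estimated from lag-1 adjacent pairs only; exchangeable or
  unstructured working correlations are out of scope, as are
  small-sample sandwich corrections.
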