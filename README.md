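# kfprog — noise-aware identification of glaucoma progression

Open-angle glaucoma is monitored with visual-field tests and pressure
readings whose results are noisy: mean deviation (MD, dB), pattern
standard deviation (PSD, dB) and intraocular pressure (IOP, mmHg) all
fluctuate from visit to visit for reasons unrelated to true disease
change.  `kfprog` implements a pipeline for deciding, at each clinic
visit, the probability that a patient is experiencing *significant
progression*, while accounting explicitly for process and measurement
noise:

1. **State-space denoising.** The 9-dimensional disease state (level,
   velocity, acceleration of MD, PSD, IOP) follows a linear-Gaussian
   model α_ij = T α_ij−1 + w_ij, observed as z_ij = H α_ij + v_ij.
   A Kalman filter produces per-visit state estimates α̂_ij; shared
   population parameters (Q, R, baseline moments) are estimated by EM
   with a Rauch-Tung-Striebel smoother.
2. **Progression labels.** Visit *j* is labeled progressed when MD has
   lost ≥ 3 dB from baseline *and* the loss recurs at a later visit
   (validation against noise), or when the visit's severity stage
   (early / moderate / severe, MD-threshold staging) worsens from
   baseline.
3. **Marginal regression.** A from-scratch GEE logistic regression
   (logit link, Bernoulli variance, scale φ = 1, AR(1) working
   correlation ρ^|s−t|, robust sandwich covariance, forward variable
   selection at α = 0.10) maps per-visit covariates to a progression
   probability.
4. **Evaluation.** Two arms — covariates from Kalman state estimates
   versus covariates from raw measurements — are compared on identical
   patient-level 10-fold cross-validation splits via averaged ROC
   curves, per-fold AUC, and fitted-probability separation between
   progressing and nonprogressing instances.

Because suitable clinical-trial data are not publicly available, the
package ships a synthetic trial-like cohort generator (six-monthly
visits, mean ≈ 15 visits per patient, a progressing subpopulation,
censoring at treatment escalation) with known ground-truth states, so
every stage is testable against truth.  See `docs/methods.md` for the
model details, parameter choices and known limitations — in particular
why, on this synthetic cohort, the raw-measurement arm holds a
structural advantage in the two-arm comparison.

## Worked example

The analysis is organized as numbered drivers over the library:

```sh
python analysis/01_simulate_cohort.py --seed 1 --n-patients 500 --out results/
python analysis/02_denoise_kalman.py  --cohort results/cohort.csv \
    --truth results/cohort_truth.csv --out results/
python analysis/03_label_progression.py --cohort results/cohort.csv --out results/
python analysis/04_compare_models.py  --seed 1 --out results/
```

`04_compare_models.py` chains the whole pipeline (simulate → include →
label → cross-validate both arms) and prints:

```
cohort: 500 patients, 6177 scored visits, progression prevalence 0.249
MD MSE vs truth: raw 2.259, filtered 0.978
kalman: mean AUC 0.944 (variance 0.0001); fitted probability 0.708 progressing vs 0.113 nonprogressing (gap 0.595)
raw   : mean AUC 0.968 (variance 0.0000); fitted probability 0.772 progressing vs 0.089 nonprogressing (gap 0.683)
specificity at 95% sensitivity: kalman 0.73, raw 0.82
```

Reading the numbers: filtering more than halves the MD error against
the hidden truth (2.26 → 0.98 dB²), and both models discriminate
progressing from nonprogressing visits well (mean cross-validated AUC
0.94–0.97).  On this synthetic cohort the raw arm scores slightly
higher than the Kalman arm because the progression label is itself
computed from the raw MD trajectory, so the raw model's change-in-MD
covariate reads the label's own firing condition — a mechanical
advantage that point-level severity staging and heavy-tailed
visual-field noise would remove in clinical data (`docs/methods.md`,
Known limitations).  Outputs land in `results/`: `comparison.json`,
`mean_roc.csv`, `fold_aucs.csv` and `roc_curves.png`.

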