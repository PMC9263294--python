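# Methods

## Scope and model overview

`slesurv` implements a survival-analysis scheme for hospitalized-SLE
cohorts in which roughly 44% of patients are lost to follow-up and the
followed portion is imbalanced (~17% deaths). Four statistical components
share one data representation — an encoded, min-max-normalized feature
vector per patient plus an outcome (0 survive / 1 death / unknown) and a
follow-up time in years:

* a cost-sensitive semi-supervised neural classifier of the survival
  outcome;
* a repeated-retraining root-cause analysis (WJR subgroups, death threat
  coefficient);
* LASSO screening followed by forward-stepwise Cox selection and
  Kaplan–Meier curves;
* a logistic survival-risk score thresholded at zero.

## The loss function

The classifier minimizes

    Loss = dyn_weight_MSE(y1, out_x1) + α(t) · dyn_weight_MSE(y2, out_x2)

with `dyn_weight_MSE(y, out) = (1 / (2·batchsize)) Σ_i w_i Σ_k (y_ik − out_ik)²`.

Design readings that the loss definition leaves open, and how this
implementation resolves them:

* **Per-sample weights inside the sum.** The weight of sample i is
  `w_i = (1 − y_i)·zero_weight + y_i·one_weight` with
  `zero_weight = Np/N`, `one_weight = Nn/N` recomputed once per batch
  (Np deaths, Nn survivors, N batch size). Treating "Weight × MSE" as a
  scalar product would collapse the per-sample construction, so the weight
  multiplies each sample's squared-error sum.
* **t counts epochs.** The ramp breakpoints (T1 = 100, T2 = 600) are the
  same order as a plausible epoch budget and far larger than the number of
  batches per epoch on a few hundred balanced records, so α(t) advances
  per epoch. This is a config choice (`LossConfig`), not hard-coded.
* **Degenerate single-class batches** receive weights (0, 1) or (1, 0)
  exactly as the definition dictates — an all-survivor batch contributes
  no gradient. No epsilon floor is applied; with batch size 32 on
  balanced data such batches are rare.
* **Pseudo-label ties** (output exactly 0.5/0.5) are assigned survival,
  the majority class, deterministically.

## Network and training

The network is 117 → 64 → 64 → 2 with ReLU hidden layers, a softmax head,
one-hot targets ((1,0) survive, (0,1) death) and plain SGD at learning
rate 0.002, batch size 32. MSE-on-softmax is an unusual pairing but is
what the loss definition states; the softmax Jacobian is applied exactly
in the analytic gradient. The implementation is direct numpy: the
architecture is tiny, a training run is seconds of CPU matrix algebra,
and a self-contained implementation keeps every run bit-reproducible from
a single seed (initialization, batch order and under-sampling all flow
from one `numpy.random.Generator`).

Defaults: 800 epochs (chosen > T2 = 600 so the pseudo-label ramp
completes), α_f = 3. The four training steps: (i) supervised fit on the
1:1 under-sampled labeled training set; (ii) argmax pseudo-labeling of
every censored record; (iii) retraining with the combined loss, pairing
one true-label batch with one pseudo-label batch per gradient step and
cycling the smaller set — the labeled portion is re-under-sampled (fresh
seeded draw) by default; (iv) final test-set prediction. Training history
records the supervised and pseudo terms separately, so the α(t) = 0 phase
is auditable.

## Synthetic cohorts

Real cohorts of this kind are not publicly deposited, so every stage is
exercised on a seeded generator whose defaults encode the study
conditions: 2444 patients, 1074 censored, labeled death fraction
233/1370, and per-feature survival/death-group prevalences calibrated to
the published group summary table (e.g. cardiopulmonary involvement
0.1750 survival / 0.3562 death; SLEDAI at discharge 5.69 ± 6.08 vs
8.77 ± 10.04). Stand-in manifestation columns pad the inventory to the
117-column encoded width of the real data.

Generation model, and what it does and does not emulate:

* **Event times** are exponential with rate
  `baseline_hazard · exp(Σ w_j x̃_j)` (continuous features z-scored
  against the survival group, binary features as 0/1), with the death
  horizon at 15 years. No time model is claimed for the real cohort; the
  exponential is the simplest law sufficient for KM/Cox recovery checks,
  and the spec of the generator keeps Weibull-style extensions behind the
  same interface.
* **Two outcome modes.** `group_first` (default) draws the outcome label
  first, features conditional on the group, and the event time from the
  exponential conditioned on the assigned outcome (deaths truncated to
  the horizon; survivors administratively censored at the horizon). This
  calibrates exactly to the published group prevalences but is not a
  proportional-hazards law. `hazard_driven` draws features from the base
  population and derives the outcome from the time law; it obeys
  proportional hazards exactly and backs the Cox/KM parameter-recovery
  tests. Using one mode for prevalence calibration and the other for
  hazard recovery is deliberate: a single mode cannot do both exactly.
* **Censoring.** Censored records keep their features, hide the outcome,
  and record a uniform lost-to-follow-up time. Their latent death
  fraction defaults to 0.43 — higher than the labeled 0.17 — emulating
  the death enrichment among lost-to-follow-up patients that
  pseudo-labeling is meant to exploit; the latent outcome is retained in
  `outcome_true` (ground truth available only in simulation).
  `medication_dependent` mode instead selects who is censored by a
  logistic tilt on the prednisone/cyclophosphamide columns (censoring at
  random given treatment, not completely at random); in that mode the
  labeled/censored death fractions emerge from selection.
* **Not emulated:** free-text clinical descriptions (the generator emits
  already-encoded features), within-patient feature correlation beyond
  what group conditioning induces, calendar-time admission structure, and
  competing risks. Tests passing on these cohorts therefore validate the
  machinery and its claimed mechanisms, not clinical performance on real
  h-SLE data.

## Data handling

One-hot encoding gives every level of a categorical column (including
binary 0/1 columns) its own indicator, so each encoded block sums to 1
rowwise and the map is invertible; unseen levels at transform time raise
an error naming the column. Min-max normalization maps constant columns
to zeros with a warning rather than dividing by zero. The train/test
split is stratified on outcome × survival-time quintile ("grouped by
survival time" is read as stratification, which preserves comparable
outcome rates and time distributions across splits); the total train size
is `round(n · ratio)` with largest-remainder allocation across strata, so
1370 labeled records at 0.8 give exactly 1096/274. Majority
under-sampling keeps every minority record and a seeded uniform draw of
equal size from the majority.

## Summary statistics

Percentages round half-up to two decimals (matching how clinical tables
print n (%) cells). Group comparisons: two-sided Mann–Whitney U for
continuous variables (asymptotic, tie-corrected, for groups over 20);
Pearson χ² without continuity correction for 2×2 tables (correction
available as a flag — the original software behind the reference values
is unknown, and plain Pearson is the conventional default).

## Root-cause analysis

R = 20 retrainings by default; each run reseeds both the under-sampling
draw and the network training, since both are real sources of prediction
instability. WJR boundaries are strict inequalities: records at exactly
0.25 or 0.75 fall in "other". Dtc ratios with a zero or undefined
denominator are reported as NaN and never flagged (a warning is logged);
this arises naturally when a single feature dominates the classifier, in
which case the misjudged groups are near-deterministic in that feature.
Dtc is computed on the held-out internal-validation (test) records.

## Survival factors

LASSO screening uses logistic-loss L1 (outcome screening before Cox,
rather than penalizing the Cox likelihood itself) over a log-spaced λ
grid, with the λ minimizing 5-fold cross-validated log-loss. Stepwise
Cox uses likelihood-ratio p-values for both entry (&lt; 0.05) and removal
(&gt; 0.10), capped at 20 steps; lifelines' Efron-tie partial likelihood
is the underlying fitter, and the null-model log partial likelihood is
evaluated in closed form. An empty selected model is a valid outcome.
Only followed records enter Cox/KM; survivors contribute censoring times
at the horizon.

## Risk score

The logistic fit is effectively unpenalized (C = 10⁶); zero training
error implies a separating hyperplane and hence a divergent MLE, in which
case the model refits with a mild ridge (C = 1) and carries a
`separation_flagged` marker. Scores at exactly the threshold classify as
survival, completing the two strict inequalities of the decision rule.
At T = 0 the rule is provably identical to thresholding the fitted
probability at 0.5, which the tests assert record by record.

## Problem sizes used in tests and the acceptance script

The semi-supervised mechanism check runs the full-size cohort (2444
records, 117 features) with default hyperparameters over 10 paired seeds.
Parameter-recovery checks use n = 1000–2000 with 10 seeds. The root-cause
replicate check uses a 20-feature cohort of 1600 records with 10
retrainings at a proportionally shortened ramp (150 epochs, T1 = 20,
T2 = 100) — the ramp geometry, not its absolute length, is what the
mechanism needs, and the shorter schedule keeps replicate retraining
cheap. The acceptance script mirrors these sizes and averages the paired
sensitivity comparison over 3 seeds.

## Known limitations

* The MSE-on-softmax loss has weak gradients at confident outputs; at the
  default learning rate small toy problems converge slowly (tests use a
  higher rate for toy fixtures).
* The generator's `group_first` mode is not a proportional-hazards law;
  Cox coefficients estimated on such cohorts are calibration-biased by
  construction (use `hazard_driven` for inference checks).
* Stepwise selection inherits the usual caveats (post-selection inference
  is not adjusted); the step log makes the path auditable.
* NRI/IDI use the two-category (single-cut) form; multi-category NRI is
  out of scope.
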