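# Methods

`mdd2ad` predicts progression from major depressive disorder (MDD) to
Alzheimer's disease (AD) in longitudinal, ICD-coded claims data by
combining a causal-inference model with machine-learning models:

1. a **marginal structural model (MSM)** fitted by weighted least squares
   with **stabilized inverse-probability-of-treatment weights (IPTW)**,
   which yields the probability `pMSM`;
2. a **multilayer perceptron (MLP)**, yielding `pANN`;
3. an **integrated predictive model (IPM)**: a gradient-boosted
   classifier over the two-column stack `[pANN, pMSM]`.

All components run on synthetic cohorts from the bundled claims
simulator, so nothing requires access to restricted Medicare data.

## Cohort and feature definitions

A patient enters the analysis with at least one MDD-coded claim
(ICD-9-CM `296.2X` before 2016, ICD-10-CM `F32.X` from 2016; an extended
registry adds the recurrent families `296.3X`/`F33.X` but is never
merged silently). Progression means a first AD-coded claim (`331.0`;
`G30.0/.1/.8/.9`, exact match) in a *strictly later* year than the first
MDD claim; ties at year resolution are excluded because precedence
cannot be established, as are records where AD precedes MDD. Controls
are an equal-size simple random sample of patients who never progressed.

Nine predictors are derived per patient: age band, gender, race,
rural/urban county, county health-professional-shortage (HPSA) class,
any comorbidity (any non-MDD/non-AD claim), follow-up (at least two
MDD-coded claims — "visits" are operationalized as distinct MDD claims),
total utilization days over claims from the first MDD year onward, and
the MDD claim count. Categoricals are one-hot encoded against fixed
vocabularies with the first level as reference; numeric features are
z-scored for the MLP using training-split statistics only.

## Stabilized weights and the MSM

For exposure history `E_0..E_T` (E_t = any MDD claim in year t, with
`E_0 = 1` by cohort definition) the stabilized weight is

    sw = prod_t P(E_t | E_{t-1}, X_0) / P(E_t | E_{t-1}, X_0, X_{t-1})

using the probability of the realized exposure level in both factors.
The numerator conditions on the baseline covariates `X_0` as well as
past exposure (the implemented form); `numerator_mode="marginal"` gives
the conventional covariate-free stabilized numerator, under which the
t = 0 factor becomes informative. The denominator conditions on the
*lagged* time-varying covariates `X_{t-1}` (yearly comorbidity flag,
yearly utilization days, cumulative MDD claim count), following the
one-year-lag convention.

Both probability models are pooled-over-time logistic regressions with
year fixed effects (per-year fits are a config option for large panels).
Degenerate year indices (no exposure variation — always true at t = 0
here) contribute a factor of exactly 1. Perfect separation falls back to
an L2-penalized fit with a logged warning. Denominator probabilities are
floored at 1e-6 (count reported); percentile truncation of weights is
off by default.

The outcome model is a **linear probability model**: weighted least
squares of the binary outcome on the encoded predictors with the
stabilized weights and HC1 robust standard errors. Predictions are the
linear predictor clipped to [0, 1]. Aliased design columns are dropped
with a warning. Feature ranking sorts the WLS coefficients descending
and stars p < 0.05; because categoricals are one-hot encoded, ranking is
per encoded column, with an optional per-variable aggregation that
represents each variable by its largest-|coefficient| indicator.

## MLP base learner

One hidden layer of 6 ReLU units, L-BFGS solver, alpha 1e-8, tolerance
1e-3, learning-rate init 0.1, max 1,200 iterations, random state 4 — a
small-cohort configuration. "Hidden layers of 6" is read as one layer of
six units; deeper stacks are available through `hidden_layer_spec`.
Feature importance is the sum of absolute first-layer weights per input;
its p-value is a one-sample t-test of the ~6 signed weights against mean
zero, which has very low power by construction and is reported as such
(missing when only one hidden unit exists).

## Stacking

The meta-learner is a gradient-boosted classifier (random state 28, 100
trees, learning rate 0.01, depth 3, 60% subsampling without replacement)
over exactly `[pANN, pMSM]`. Stack features for training are
**out-of-fold** base predictions from 5-fold refits of the training
partition. The naive alternative — in-sample base predictions — was
measured to let the overfit perceptron dominate the meta-learner: over
40 replicates of the dual-signal design the in-sample ensemble averaged
test AUC 0.788 against base means of 0.801 (MSM) and 0.793 (MLP), while
the cross-fitted ensemble averaged 0.804. Cross-fitting is therefore the
default and the in-sample variant remains available via
`cross_fit=False`. Weights act at fitting time only; prediction is
end-to-end from raw features and needs no weights. The classification
threshold defaults to 0.5 (configurable).

## Evaluation

Positive class: progressed to AD. The panel comprises the confusion
matrix, per-class precision/recall/F1 (the remained-MDD column swaps the
positive class), accuracy, overall precision/recall/specificity, and AUC
by the trapezoidal rule over the empirical ROC (midrank tie handling;
identical to the normalized Mann–Whitney U statistic). The AUC interval
is a stratified percentile bootstrap (2,000 resamples, seeded); the
Hanley–McNeil asymptotic interval is available via `method="hanley"`.
Undefined ratios are reported as missing, never silently NaN. AUC above
0.80 is flagged as crossing the conventional clinical-relevance line.
Ratios are reported to 2 decimals and percentages to 1, matching the
conventional table precision.

## Sensitivity protocol

40% of predictor cells are masked completely at random (the outcome and
identifier columns are never touched), then multiply imputed m = 5 times
by a data-augmentation Gibbs sampler under a joint multivariate-normal
model: each sweep draws (mean, covariance) from their posterior given
the current completed matrix (Jeffreys prior), then redraws missing
cells column-by-column from the univariate conditional normal given all
other columns — a systematic-scan update of the same joint model, chosen
over per-row-pattern conditional draws purely for speed. Default burn-in
is 50 sweeps; chains are independent and seeded per imputation.
Categoricals are level-index coded before imputation and decoded by
nearest-level rounding — a known mismatch of the normal model, accepted
deliberately as the simple joint-model compromise (chained equations are
out of scope). Observed cells are returned bit-identical.

On each completed table the full ensemble (with `pMSM`) and an MLP-only
model are refitted with the identical train/test split and evaluated;
metrics are pooled as per-dataset means (a `single-dataset` mode uses
only the first imputation). Refitting is the default; a re-score mode
applies the already-fitted primary models to the imputed test rows
instead, and reports name the mode. With a masking rate of 0 the
protocol reduces exactly to the primary analysis.

## Synthetic cohort generator

The simulator emulates the structure the pipeline assumes, not Medicare
billing semantics. Per patient: demographics drawn from configurable
prevalences (defaults are the pooled published descriptive frequencies,
for face validity); a latent standard-normal frailty `U` entering only
the outcome hazard (unmeasured confounding stand-in); a yearly binary
comorbidity burden `Z_t` that persists, rises after past MDD exposure,
and drives both future exposure (`confounding_strength`) and the outcome
— a genuine time-varying confounder; yearly exposure `E_t` (MDD claim)
with `E_0 = 1` (cohort entry is the first MDD diagnosis); and a
discrete-time logistic progression hazard from year 1 on, driven by
cumulative exposure (`exposure_effect`), current `Z`, age band, `U`, and
a balanced ±1 interaction of gender and HPSA-partly (`nonlinear_effect`)
that main-effects models cannot represent — the "dual signal" that gives
the linear-causal and nonlinear learners complementary material. ICD-9
codes are emitted through 2015 and ICD-10 from 2016. Claims for
progressors stop at the event year (`truncate_at_event=True`); Monte-
Carlo designs that regress an end-of-window outcome on cumulative
exposure must set it to `False`, because event-time truncation otherwise
induces a mechanical negative exposure–outcome association.

Balanced case/control cohorts are produced by accumulation: batches are
simulated from the natural process until both groups reach the requested
size, keeping the first `n_per_group` of each in simulation order —
bit-identical under a fixed seed. Controls never receive an AD code
within the window (the natural reading of "remained MDD").

Structural defaults (logit scale: baseline exposure −2.2, baseline
comorbidity −1.2, baseline hazard −3.2, exposure persistence 0.8,
comorbidity persistence 1.0, exposure→comorbidity feedback 0.8,
covariate→outcome 0.8, age 0.25 per band, confounding 1.0, exposure
effect 0.35 per cumulative claim, latent 0.8, nonlinear 1.0) were chosen
once to give a sparse, claims-like stream (mean MDD claim count near 2,
total utilization near 10–16 days) and a cumulative progression risk
near 30% over the 8-year window. What the simulator does **not** emulate:
enrollment gaps and censoring, sub-year claim dating, realistic code
mixes beyond the MDD/AD/comorbidity sets, propensity-matched controls,
or missingness mechanisms other than MCAR. Passing tests therefore show
that the pipeline's machinery is correct and behaves as the theory
predicts under its assumed data-generating structure — not that the
published effect sizes transfer to real claims.

## Reproducibility and problem sizes

Every stochastic stage derives its seed from the master seed and a stage
tag (SHA-256, below 2^31), so full runs are bit-reproducible and stages
never share streams. The bundled statistical checks use: saturated
two-period panels (n = 300–400) for exact weight-oracle equality; a
5,000-patient null simulation for weight cancellation; 200 replicates of
a 2,000-patient confounded design (untruncated follow-up) for
confounding-bias reduction, with the estimand defined by a 100,000-
patient randomized-exposure run; and 50 replicates of the 282-per-group
dual-signal design for the stacking and sensitivity direction
properties, with m = 5 imputations and a 20-sweep burn-in inside the
Monte-Carlo loop.

## Known limitations

- The MSM is a linear probability model: predictions need clipping and
  coefficients are not risk ratios.
- The printed-form stabilized numerator conditions on baseline
  covariates; with the default covariate numerator the t = 0 factor
  always cancels, so baseline exposure imbalance is not reweighted.
- The MVN imputer treats categoricals as continuous and rounds back;
  rare levels can be under-imputed.
- The first-layer-weight t-test treats ~6 weights as a sample; it is a
  screen, not a calibrated test.
- No censoring weights: patients are assumed observed over the whole
  window, as in the generator.
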