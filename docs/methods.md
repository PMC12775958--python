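# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## Feature definitions

Cortisol is sampled at an arrival occasion and at six post-rest occasions
T1..T6; T1 is the baseline. The default grid places T1 at minute 0, the
stressor at minutes 0–15, and T2..T6 at 20-minute intervals (20, 40, …,
100); the arrival sample sits at −30 min. The sampling labels in common
use ("post", "+20 min post", …) are anchored to the end of the stressor,
so the "+20 min post" sample is the grid point at minute 40. Both grids
are configurable because AUCi magnitudes depend on them. Cardio phases
(baseline, preparation, speech, mental arithmetic, recovery) default to
minutes 0, 5, 10, 15, 50 — readings taken at the third minute of each
5-minute phase, recovery at 35 min after the stressor.

- **AUCi** is the trapezoid of the series minus the baseline rectangle.
  Cortisol AUCi uses T1..T6 only (the arrival sample is excluded from
  every feature). Cardio AUCi uses all five phases including recovery by
  default; `include_cardio_recovery_in_auci=False` restricts it to
  baseline + stressor phases, since either convention appears in
  practice.
- **Peaks**: cortisol over T1..T6; HR over baseline + the three stressor
  phases; MAP over the three stressor phases only. Ties break to the
  earliest occasion.
- **Recovery** is the raw level at T6 (cortisol) or the recovery phase
  (MAP, HR) — a level after a fixed duration, not a time-to-baseline,
  which single-occasion protocols cannot measure.
- **Responder rule**: a participant is a cortisol non-responder when the
  post-baseline peak rises strictly less than 15.5 % above baseline;
  exactly 15.5 % counts as responding.
- **KNN imputation** replaces a missing cell by the mean of that variable
  over the k = 5 nearest fully observed rows, with standardized Euclidean
  distance computed on the variables the incomplete row has. It is meant
  for the < 5 % missingness this protocol produces and refuses anything
  heavier.

## Trajectory GAMs

Each modality (cortisol split into responders and non-responders; MAP and
HR on the full sample) is modelled as a gamma GLM with log link,

    log E[y_ij] = β0 + f(t_ij) + g_i(t_ij),

with `f` a cubic B-spline population smooth (6 basis functions on these
5–6-point grids, second-difference penalty, sum-to-zero constraint) and
`g_i` per-participant spline deviations under a shared ridge penalty —
the factor-smooth analogue of random intercepts plus random curves. The
deviation curves deliberately use a smaller basis (4 functions) than the
observation count so they cannot interpolate the data.

For the gamma/log-link family the IRLS working weights are identically 1,
so each iteration is a penalized least-squares solve of the working
response. The per-participant blocks make the penalized normal matrix an
arrowhead system; it is solved by Schur complement on the small fixed
block, which costs O(n_participants · basis³) per smoothing-parameter
candidate and makes the GCV grid search cheap. Smoothing parameters
(population-smooth penalty and random-curve ridge) are selected by GCV on
the converged working model, over log-spaced grids (10⁻³…10⁵ and
10⁻³…10³), with two selection rounds interleaved with IRLS refits.
Convergence is declared at a relative deviance change below 1e-8 (max 200
iterations).

Reported diagnostics: per-term effective degrees of freedom
(edf = p − tr((XᵀX+S)⁻¹S) split over blocks), deviance explained
(1 − D/D₀, reported as 1 for a degenerate noiseless constant fit where
D₀ = 0), adjusted R² on the response scale, and the Pearson scale
estimate. Timepoint contrasts are Wald tests of the population smooth
against baseline on the link scale, with the penalized coefficient
covariance, adjusted by Hommel's procedure (closed testing with Simes
local tests; delegated to statsmodels and verified against a brute-force
closed-testing oracle in the tests).

This B-spline formulation is a practical stand-in for a Gaussian-process
smooth: on grids of five to seven timepoints the two span essentially the
same function class. Reproducing any specific published software's REML
machinery is a non-goal, as is reproducing diagnostics of data that were
never deposited.

## Composite index

Reactivity (three AUCi features) and recovery (three raw levels) each
enter a correlation-matrix PCA after per-feature normalization. Default
transform assignments: scaled inverse hyperbolic sine
(`asinh(x / median|x|)`) for cortisol and HR AUCi, which can be negative;
natural log for MAP AUCi and for cortisol/MAP recovery; none for HR
recovery. The choice is validated against the data: a log-assigned
feature falls back to the scaled asinh when it contains non-positive
values or when asinh leaves the column less skewed than log does (the log
of a near-zero area otherwise manufactures a many-sigma outlier). Every
fallback is recorded in the PCA report.

The leading eigenvector is oriented so its loading sum is positive —
which, for the positively intercorrelated blocks this design produces,
makes every feature correlate positively with its score. Scores are
eigenvector projections of the standardized data scaled to unit variance;
loadings are reported as eigenvector × √eigenvalue; components with
eigenvalue > 1 are counted as retained, and downstream stages always use
the leading component. Scores are standardized to T-scores
(50 + 10·z, sample SD with n−1), and the index is the negated geometric
mean of the two T-scores. T-scores sit 5 SD from zero, so a non-positive
T-score is possible only for a > 5-sigma outlier; the index then raises
an error rather than clamp, since a geometric mean of a non-positive
value is meaningless. Both responders and non-responders enter the PCAs.

## Validity regression

Distress is regressed on the mean-centered index, mean-centered daily
stressors, their product, major life events, and seven demographic
covariates (gender, age, education, marital status, employment, income,
medical condition — the covariate set is configurable). Centering the two
interacting terms leaves the product coefficient identical to the
uncentered fit and removes main-effect collinearity. Standardized betas
z-score the outcome and continuous regressors and leave binaries 0/1;
partial η² uses the single-df identity t²/(t² + df_resid). No
multiplicity correction is applied inside this single confirmatory model.

## Predictor selection

The LASSO objective is (1/2n)‖y − Xβ‖² + λ‖β‖₁, solved by cyclic
coordinate descent with soft thresholding on the Gram matrix,
warm-started along a descending path of 2000 log-spaced λ values from
λ_max (= max|Xᵀy|/n on the standardized data, the smallest all-zero
penalty) down four decades. Convergence: largest coefficient change in a
full sweep < 1e-7, with active-set polishing between sweeps; the kernel
is numba-compiled. Predictors are standardized inside each training set
(binaries included, coded 0/1); reported coefficients are back-transformed
to the original predictor scale; the intercept is never penalized.

The procedure: augment the original sample to 500 rows by resampling with
replacement; select λ by 10-fold cross-validation repeated 50 times
(fresh random partitions per repeat; per λ, the mean of the 500 held-out
fold RMSEs; ties go to the larger λ); compute coefficients on the full
augmented sample at λ_min; rescale |coefficients| (standardized scale) to
0–100 importance with the largest magnitude at 100; refit once on the
original participants for in-sample RMSE, MAE and R². Predictors with
importance ≥ 10 form the "identified" set.

Drawing folds on augmented rows lets copies of one original row appear in
both train and test folds. That leakage is retained deliberately in the
default because it is part of the procedure being reproduced; it biases
λ_min low and the identified set large. `grouped_folds=True` provides the
leakage-free variant — folds partition original-row identities — which
selects substantially larger penalties and much sparser models, and is
what the planted-recovery acceptance check uses, since calibrated
selection is exactly what leakage destroys.

## Synthetic cohort design

The generator is the ground truth for every stage. Per participant it
draws a standardized latent resilience factor; a reactivity factor and a
recovery factor each load on its negation with coupling 0.72; each
modality's reactivity/recovery latents load on those with loading 0.60,
and each modality's baseline latent loads on its recovery latent with
0.25 (higher baseline physiology ⇒ slower recovery, so baseline levels
genuinely predict the index — mirroring field observations). Trajectory
parameters are monotone maps of the latents:

- cortisol baseline: log-normal, median 1.06 ng/ml, log-SD 0.72 (matches
  a mean near 1.38 and SD near 1.0);
- responders: log-linear rise from T1 to the grid point nearest
  T1 + 35 min (peak = baseline·(1 + rel. amplitude), amplitude log-normal
  with median 1.6), log-linear decay to 0.85× baseline at T6; arrival
  sample 1.25× baseline;
- non-responders: arrival peak at 1.5× baseline, monotone log-linear
  decline to 0.60× baseline — so the downstream 15.5 % rule recovers the
  labels (>99 % agreement at the default noise);
- MAP/HR: baselines N(81, 9²) and N(67.75, 9.5²); phase offsets at their
  observed means (speech peak +26.3 mm Hg, +24.9 BPM) scaled by a
  log-normal participant reactivity factor (log-SD 0.2); the recovery
  occasion gets its own offset (mean +1.39 mm Hg for MAP, 0 for HR — MAP
  stays above baseline in expectation, HR returns to it) with SD 4.5.
- noise: multiplicative log-normal for cortisol (log-SD 0.08, an assay +
  sampling CV of ~8 %); additive for MAP (1.5 mm Hg) and HR (2.0 BPM) —
  cardio occasions are three-reading phase averages, hence the small SDs.
  SBP/DBP are emitted consistently with the latent MAP via a
  participant-level pulse pressure (42 ± 8 mm Hg), so the MAP formula is
  exercised end to end.

These couplings were fixed once so that, at n = 248, the two PCAs explain
≈ 48 % (reactivity) and ≈ 43 % (recovery) of their blocks and the T-score
correlation between reactivity and recovery lands near 0.5 (generator
design band 0.3–0.6) — the correlation structure the pipeline is meant to
operate on.

Predictors: 48 named candidates. The three baseline-physiology columns
are the participant's actual simulated baselines (mechanistically
associated with the index). The remaining 45 derive from latent Gaussians
drawn conditionally on the participant's noise-free index: a planted
predictor with coefficient w has latent `w·z(index) + √(1−w²)·ε`, i.e.
the coefficients are index loadings on the correlation scale. The default
plants ten predictors at |w| = 0.3; jointly they account for
10·0.3²/(1 + 9·0.3²) ≈ 50 % of the index variance. Binary predictors
threshold their latents at the configured prevalences (e.g. 15.3 % for
medical conditions); age, stressor counts and scores are affine/rounded
maps of theirs. The "noise-free index" is obtained by pushing each
participant's noiseless trajectories through the package's own feature
and composite stages, so planted predictor–index and index–distress
effects refer to exactly the quantity the pipeline computes, up to
measurement noise (the measured index correlates ≈ 0.98 with it).
Distress is `20 + β·(index − mean) + 0.08·(daily − 50) + 0.8·major + ε`,
ε ~ N(0, 7²), with β = −0.25 per index point by default (standardized
≈ −0.29).

What the generator does **not** emulate: circadian cortisol rhythm and
the awakening response, inter-assay drift, beat-to-beat HR variability,
item-level questionnaire structure, non-Gaussian distress (the outcome is
conditionally normal), and informative missingness (only MCAR is
provided). Passing tests therefore demonstrate that the pipeline's
statistics are calibrated and its algorithms correct under the stated
generative structure — not that the index is valid in any particular
human sample.

## Problem sizes used in the checks

The simulation-based checks run at the study's scale, chosen as the
natural operating point of the pipeline: cohorts of n = 248 (500
Monte-Carlo replicates for CI coverage of the validity regression; 20
seeded end-to-end runs for planted-predictor recovery; n = 1000 for the
responder-rule agreement), 1000 random series for the AUCi oracle and
1000 random vectors (m ≤ 5) for the closed-testing oracle.

## Known limitations

- GCV on the working model can undersmooth when between-participant
  variance dominates; the reduced random basis bounds, but does not
  eliminate, this.
- The Wald contrast covariance conditions on the selected smoothing
  parameters (no selection uncertainty), as is standard.
- The importance-≥-10 rule is a reading convention, not an error-controlled
  selection procedure; under the leaky default CV it over-selects by
  construction.
- `simulate_cardio`'s per-phase offsets are exchangeable with any design;
  only the default offsets encode the speech-phase peak.
- The index errors on non-positive T-scores instead of winsorizing;
  pipelines feeding it extreme outliers must handle that error.
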