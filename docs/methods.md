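# Methods

This note documents the models, estimators, conventions, and design choices
behind `crpcsurv`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Synthetic cohort model

The generator produces the five raw tables the pipeline consumes, from a
single seed. Its purpose is structural fidelity — giving every downstream
operation exactly the kind of input it must handle — not clinical realism.

**Covariates.** `n_vars` (default 101) latent standard-normal covariates:
named variables `psa`, `comorbidity_count`, `age`, `bmi`, then lab analytes.
The first lab indices form `n_blocks` equicorrelated blocks (default 24
pairs, within-block ρ = 0.9, built as √ρ·g + √(1−ρ)·ε with a shared block
factor g); everything else is independent. Latent values are mapped to
observed scales: log-normal for the 12 log-transform ("skewed") variables —
log-PSA at diagnosis has mean 2.7 and SD 1.6, matching the real-world cohort
moments this emulates — affine (mean 100, SD 15) for other labs, a rounded,
clipped count with mean 2.5 and SD 2.0 for comorbidities (realized as that
many distinct weight-1 Charlson codes within the 2-year lookback), and
clipped affine maps for age and BMI. The last 10 variables are never written
(emulating variables a clinical system does not capture); the 7 before them
are captured for only ~20% of patients, so they exceed the 60% missingness
ceiling and are excluded downstream. This layout makes the pipeline's
variable ledger come out at 101 → 91 extracted → 84 modelled → 60 retained
by construction.

**Survival.** From each transitioning patient's index date,
T = b·(E/e^η)^{1/k} with E ~ Exp(1), η = Σ β_k z_k on the *latent
standardized* covariates, shape k = 1 (exponential) by default and scale
b = 24 months — so S(t | η=0) = exp(−(t/b)^k) and the η = 0 median is
b·(ln 2)^{1/k}, giving closed-form calibration checks. The default sparse
truth is β = +0.5 on log-PSA, +0.3 on comorbidity count, ±0.4 on two
independent labs. Censoring is administrative (uniform study entry
2008–2011, study end 2019-12-31) plus exponential dropout whose rate is
calibrated by bisection — against the actually drawn survival times and
uniforms — so the realized censored fraction hits the target (default 30%).

**PSA trajectories and the index date.** log-PSA follows a piecewise-linear
mean on a jittered 3-month grid inside the hormone-therapy episode:
declining at 0.05–0.15 /month toward a nadir at the biological transition
date, then rising at 0.10–0.25 /month, plus N(0, 0.15) noise. With
`enforce_detectability` (default) the generator guarantees the phenotype is
decidable from the written values: transitioning patients get at least one
strictly rising consecutive triple after the transition (resampling the
noise up to 20 times, then sorting the tail as a last resort), and
non-transitioning patients get none. The property tests that measure
*detection sensitivity as a function of noise* disable this guarantee.

A crucial consistency rule: the survival clock and all capture windows
anchor at the **detectable index date** — the earlier of the second-line
therapy start and the third value of the earliest rising PSA triple — which
is exactly the date downstream phenotyping will assign. Anchoring at the
latent transition date instead would let detected index dates postdate
death. One side effect: observed log-PSA *at the index date* sits slightly
above the configured nadir mean, since the index falls on the rising limb.

Lab series extend over the scheduled episode regardless of the simulated
death date; the tables are a modelling fixture, not a clinically coherent
record. Non-transitioning patients contribute exclusion-path variety
(no-hormone-therapy and fewer-than-3-PSA fractions) but never enter the
feature matrix.

## Phenotyping conventions

- "Increase" is strict; ties are not increases. No minimum rise magnitude
  or absolute PSA floor is applied — the detection rule is purely the
  two-consecutive-rises definition.
- Same-day duplicate PSA values collapse to their maximum, making results
  independent of row order.
- Hormone dispenses merge into episodes when gaps are ≤ `gap_days`
  (default 90; dispense records of intermittent therapy are gappy).
  Episode membership is inclusive of both endpoints.
- The ≥3-PSA eligibility rule counts values within the union of a
  patient's episodes; the rising triple must lie within a single episode.
- Method 1 requires the second-line start on/after the hormone episode
  start (not necessarily inside it) and dates CRPC at that start; method 2
  dates it at the third value of the earliest qualifying triple; the
  combined date is the earlier of the two.

## Feature engineering

Windows are half-open day intervals [start, end): codes in
[index − 6 mo, index + 3 mo), labs within ±3 months (≤ 91 days) with ties
in |Δt| broken toward the earlier measurement. A month is 30.4375 days
everywhere. Survival time is (death or last follow-up − index)/30.4375
months; a patient whose index postdates follow-up is a hard error.

The 12 log-transformed variables replace zeros with the column's smallest
observed positive value before taking logs; applying the transform twice
raises an error rather than silently changing scale. Imputation fits, per
incomplete column, a ridge regression on the fully observed columns using
the rows where the column is observed; the penalty is chosen by 5-fold CV
over a 25-point log grid (10⁻⁴–10⁴), solved in closed form via one
eigendecomposition of XᵀX per fold. Columns above the 60% missingness
ceiling are dropped first; columns with fewer than 10 usable rows fall back
to mean imputation with a warning. The fitted imputer is a first-class
object so cross-validation can re-fit it inside each training fold and
apply it unchanged to the held-out fold (the leak-free default throughout).
Imputation is single-pass (no chained iteration). Standardization centers
and scales continuous columns, leaves 0/1 columns alone, drops
zero-variance columns with a warning, and stores its parameters for
held-out application.

## Elastic-net Cox

Objective: −(1/n)·log PL(β) + λ[α‖β‖₁ + ((1−α)/2)‖β‖₂²], Breslow ties,
α = 0.5 by default. The coordinate-descent path is computed by
scikit-survival's glmnet-style solver, whose objective was verified to be
exactly this one (KKT residuals ~10⁻⁵ against our own Breslow gradient).
The λ grid is 100 log-spaced values from λ_max — computed from the gradient
of the null model, the smallest λ with β = 0 — down to 10⁻³·λ_max; a grid
value of 0 is fitted at 10⁻⁸·λ_max, which agrees with the unpenalized
partial-likelihood optimum to < 10⁻⁴ at the tested sizes. λ is selected by
maximizing the Verweij–van Houwelingen cross-validated partial likelihood,
ll_full(β₋k) − ll_train(β₋k), over event-stratified folds. Ties are rare on
continuous simulated times, so Breslow versus Efron is immaterial here;
lifelines (Efron at ties, Newton solver) serves as the independent
unpenalized oracle on tie-free data. The 90/10 hold-out split takes
round(0.1·n) test patients, event-stratified, and is never touched by
imputation, reduction, or λ selection.

## Feature reduction

All C(p,2) pairwise |ρ| values are partitioned into three groups by exact
weighted 1-D k-means solved with dynamic programming on the sorted unique
values — deterministic, no initialization. With fewer than three distinct
values the labels degrade gracefully (all-identical ⇒ a single "low"
cluster ⇒ nothing removed). The removal step is a vertex cover of the
high-pair graph solved exactly as two integer programs (HiGHS via
`scipy.optimize.milp`): minimize the number of removals, then — fixing that
minimum — maximize the total absolute correlation of the removed set, i.e.
prefer deleting the most redundant member of each pair. Infeasibility is
impossible (removing every high-pair vertex is always a cover).

Outcome ranking scores each variable by |2·(c − ½)|, where c is Harrell's
concordance between the single variable and survival — a censoring-aware
analogue of absolute outcome correlation, invariant to monotone transforms
(a plain Pearson correlation against observed times is not censoring-safe).
Recursive feature elimination refits the elastic net at each size, drops
the smallest-|β| variable (exact zeros first; ties broken by outcome rank,
weakest first), records the mean cross-validated iAUC at every size down to
`min_k`, and returns the size maximizing it (ties toward fewer variables).

## Evaluation

AUC(t) is the IPCW cumulative/dynamic estimator: cases are deaths by t
weighted by 1/Ĝ(Tᵢ⁻) with Ĝ the Kaplan–Meier censoring survival; controls
are patients at risk past t, unweighted; tied scores get half credit. The
iAUC averages AUC(t) over the distinct event times in [6, 30] months with
weights proportional to the Kaplan–Meier event-distribution increments
Ŝ(t⁻) − Ŝ(t) — an integral with respect to where deaths occur, renormalized
over the window (grid points with no remaining controls are dropped with
their weight). Undefined cases (no cases/controls, no events in window) are
distinct errors, never silent NaNs.

Fold-wise model comparisons use the exact two-sided Wilcoxon signed-rank
test for n ≤ 25 pairs (zero differences are dropped; an all-zero vector
gives p = 1 by convention). The single hold-out comparison instead uses a
patient-level bootstrap (1000 resamples, seeded) since folds do not exist
there. Median-split stratification sends scores ≤ median to low risk —
with odd n and distinct scores low gets the extra patient — and reports
Kaplan–Meier curves, the two-sided log-rank test, and the hazard ratio with
95% CI from an unpenalized single-covariate Cox fit.

The transfer-model comparison emulates applying a trial-derived model to
clinic data: a second cohort with a trial-like race mix (86.9% White),
fewer comorbidities (mean 1.6), higher PSA (log-mean 4.4), and its entire
effect structure moved onto different covariates. A model trained there
carries no transportable signal, so its hold-out iAUC sits near chance
while the locally trained model retains discrimination — the qualitative
pattern this pipeline exists to detect.

## Bias audit

With race excluded from the features, patients are binned by pooled
risk-score deciles (rank-based, hence invariant to monotone transforms of
the score); within each (bin, race) cell the mean audited covariate
(Charlson count or PSA) is computed. Bins where any present race has fewer
than `min_n` = 10 patients are merged toward the median bin globally, so
all races share final bin edges. The disparity gap between two races is
the mean vertical curve separation over shared bins, with a patient-level
bootstrap 95% interval.

One estimand subtlety, verified analytically and by simulation: when a
+1 comorbidity shift is planted at equal underlying risk, the
score-conditional gap is attenuated below 1 — the learned score contains
the shifted covariate, so conditioning on it absorbs roughly b²/Var(s) of
the shift (b the standardized comorbidity coefficient, s the score). At the
default effect sizes the expected recovered gap is ≈ 0.75–0.85; the
validation study reports the mean over three replicate cohorts.

## Validation studies and problem sizes

`crpcsurv.validation` regenerates everything from a seed: AUC versus an
O(n²) pair-sum oracle with its own product-limit censoring estimator (200
instances, n ≤ 50); the removal ILP versus 2^p enumeration (100 instances,
p ≤ 12); the λ = 0 fit versus lifelines (n = 40, p = 3); sparse-support
sign recovery through the *entire* pipeline — tables to fitted model — on
ten 2 000-patient cohorts; null iAUC calibration on ten effect-free
300-patient cohorts; planted-disparity recovery on three 4 000-patient
cohorts; and 95% CI coverage for a true hazard ratio of 2.7 in 100
two-group exponential replicates of 513 patients. The acceptance script
additionally runs the full experiment at 2 000 patients (513 phenotyped)
and a registry-scale phenotyping run at 17 322 patients. These sizes are
the package's study conditions; they keep every simulated quantity's Monte
Carlo error well inside the tolerances asserted in the tests.

## Known limitations

- The generator guarantees phenotype decidability by construction under its
  defaults; passing tests therefore certify the pipeline's logic, not
  real-world phenotyping sensitivity (83%-accurate chart review is the
  realistic benchmark for that).
- ICD-style codes are a minimal vocabulary sufficient for the Charlson
  grouper; procedure codes and clinical notes are not simulated.
- Censoring is independent by design; informative censoring is out of scope.
- Imputation uses fully observed predictors only; chained-equation
  refinements are deliberately not implemented.
- Stage artifacts are deterministic files, but re-running a stage always
  recomputes it; there is no hash-keyed cache (determinism makes a cache a
  pure optimization).
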