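# Methods

## Ordinary least product calibration

Two laboratories assaying the same samples both measure with error, so the
symmetric OLP (geometric-mean) line is used instead of OLS. With `x` the
test laboratory and `y` the reference laboratory,

    β = sign(S_xy) · √(S_yy / S_xx),    α = ȳ − β·x̄ .

This is the minimizer of Σ |vertical deviation| × |horizontal deviation|
(equivalently Σ (y − α − βx)² / |β|), which the test suite verifies against
a dense 2-D grid-search oracle. Two structural identities are also tested:
axis-swap symmetry (swapping x and y gives slope 1/β, intercept −α/β) and
the geometric-mean identity β = √(b_OLS(y|x) / b_OLS(x|y)).

**Regression direction.** The model is `reference = α + β·test`, so the
fitted line doubles as the harmonization equation `adjusted = α + β·raw`.
With test laboratories reading low, this direction yields β > 1 and
adjusted values above raw ones, matching the published coefficient table.

**Confidence intervals.** Default is the analytic construction:
`B = t²(1−r²)/(n−2)` with `t` the two-sided Student critical value on
`n−2` df; slope bounds `β(√(B+1) ∓ √B)`; intercept bounds from pairing each
extreme slope with the means (`ȳ − β_upper·x̄`, `ȳ − β_lower·x̄`). It is
deterministic and reproduces the published per-laboratory significance
pattern on the bundled calibration table. A pairs bootstrap (percentile,
2000 replicates, vectorized) is provided as `ci_method="bootstrap"`.

**Significance and harmonization policy.** Fixed bias ⇔ 0 outside the α
CI; proportional bias ⇔ 1 outside the β CI. Under the default
`biased_only` policy only flagged laboratories are corrected; `always` and
`never` are available. The reference laboratory is never transformed.
Corrected values below 0 pmol/L (possible for small readings with a
negative α) are clamped to 0 with a warning.

**Known limitation — interval coverage under assay noise.** Immunoassay
imprecision is multiplicative (a roughly constant CV), and a dilution
series spans a ~35-fold range with one high-leverage top point. Under that
error structure the analytic intervals, whose derivation assumes
homoscedastic errors, markedly under-cover the slope (simulated coverage
≈55% at a 95% nominal level for n = 10); the percentile pairs bootstrap
performs much better (α coverage near nominal, β coverage ≈84–90%), which
is why it is shipped as the robustness check. Under homoscedastic additive
noise the analytic slope interval covers at ≈95–96% and the intercept
interval runs slightly narrow (≈87%). The test suite asserts exactly these
behaviors. Practical reading: on real calibration tables trust the point
estimates and the qualitative bias pattern; for interval-based claims at
n = 10 prefer the bootstrap and treat marginal significance with caution.

## Two-stage covariate-adjusted ROC regression

Stage 1 (control model): OLS of the marker on covariates among controls;
designs with condition number above 1e8 are rejected with the offending
covariates named (age and menopausal state are strongly collinear in
gynecological cohorts — the default covariate set is creatinine +
menopausal state, with age handled by stratification instead).

Stage 2 (ROC-GLM): case placement values use the empirical CDF of stage-1
residuals with strict "greater than" counting, `PV_i` = fraction of
control residuals exceeding `y_i − x_i'θ̂`. For the GLM response
construction only, PVs are clipped to `[1/(2n₀), 1 − 1/(2n₀)]` so grid-end
indicators are not degenerate. The binary indicators `U_iu = 1{PV_i ≤ u}`
over an FPR grid follow a probit-link binomial GLM with linear predictor
`γ0 + γ1·Φ⁻¹(u) + β'X_i`, fitted by IRLS (statsmodels); non-convergence
and all-extreme placement values raise informative errors.

**FPR grid.** Default 30 equally spaced interior points
`{1/31, …, 30/31}`; endpoints are excluded because Φ⁻¹ diverges there.
Results are insensitive to grid size beyond ~15 points; coverage
simulations in the test suite use 15 points for speed.

**Covariate-specific summaries.** `ROC_X(u) = Φ(γ0 + γ1·Φ⁻¹(u) + β'X)`
and the closed-form binormal AUC `Φ((γ0+β'X)/√(1+γ1²))`, verified against
numerical quadrature of the fitted curve.

**Cluster bootstrap.** Hospitals are resampled with replacement (as many
as observed), the full two-stage procedure is refitted per replicate
(warm-started at the full-data estimates), and percentile intervals are
formed. Replicates where a resample lacks cases or controls are discarded
with a log entry; more than 20% discarded is an error. The replicate RNG
is seeded with the (seed, replicate-index) pair, so runs are reproducible
and adjacent seeds do not share streams. The default of 50 replicates
mirrors the original analysis setting; coverage studies in the test suite
use 200 replicates per fit, because 2.5%/97.5% percentile endpoints cannot
be estimated stably from 50 draws (at 50 draws, measured coverage of a
null covariate's 95% CI drops to ≈83%). Cluster count matters too: with
twelve simulated clusters the measured null coverage is 92/100, while at
the six clusters typical of a multicenter study it is 87/100 — percentile
intervals from very few resampled clusters are known to run a few points
narrow. Interval-based claims from a six-hospital bootstrap should
therefore be read as approximate; the suite asserts nominal-range coverage
in the twelve-cluster regime and documents the six-cluster shortfall here.

## ROC utilities

Positivity is strict `>` everywhere (a value equal to the cut-off is
negative), anchored by the conventional CA125 rule ">35 IU/mL". Empirical
ROC curves are evaluated at every unique observed threshold; ties between
a case and a control count ½, so the trapezoidal AUC equals the
Mann–Whitney estimate (asserted against `scipy.stats.mannwhitneyu`).

The Youden cut-off maximizes J = Se + Sp − 1 over observed scores; among
equal-J thresholds the smallest is returned (maximizing sensitivity), and
with the default `rounding="integer"` the selected threshold is rounded to
the nearest whole unit *after* maximization — a reporting convention for
clinical cut-offs.

The paired AUC comparison is DeLong's test: per-subject placement
components give the covariance of the two AUC estimators; the variance of
the difference feeds a two-sided normal test. For a mean-like statistic
this variance is algebraically close to the grouped leave-one-subject-out
jackknife, which the tests verify at n = 50/50. Identical markers return
p = 1 with a warning; zero variance with a nonzero difference is an error.

## Study pipeline

Eligibility rules are screened in a fixed order (creatinine outside
(0.3, 3] mg/dL; missing/unknown diagnosis group; missing age;
premenopausal with age > 55; age outside 18–70) and each excluded record
is logged under the first rule it violates, so the log sums to the input
count. Strata are pre/post-menopausal split at 40/60 years with "≤" on the
lower side. Each stratum × contrast (malignant vs all others; malignant vs
benign only) derives its own HE4 Youden cut-off, dichotomizes HE4 and
CA125 (35 IU/mL), and compares the two dichotomous AUCs with the paired
DeLong test; for a binary marker the AUC equals (Se+Sp)/2, which is what
the stratified comparisons effectively contrast. The sensitivity analysis
keeps only ovarian, annexal and peritoneal lesions and endometriosis in
the benign group.

The enrollment calculation is the normal-approximation sample size for a
sensitivity estimate: `n_cases = ⌈z²·Se(1−Se)/d²⌉` with d the CI
*half-width*, inflated by prevalence, cases rounded up before the
prevalence division and the total rounded up (with prevalence 0.20,
Se 0.85, 95% confidence, d = 0.05: 196 cases → 980 subjects). The
half-width reading of "CI width" is adopted because only it reproduces the
published total.

## Synthetic data generator

The generator supplies study-shaped data with known truth; no
individual-level cohort is deposited.

*Calibration experiments.* Each laboratory reads the shared ten-point
dilution series (30.3–1074.4 pmol/L) through the inverse of its bias map,
`r = (true − α)/β`, in duplicate, with multiplicative Gaussian noise at
the platform CV (defaults: 3.2% Lumipulse, 10% Cobas and Architect, 4.9%
Alinity — the manufacturers' declared totals). Duplicates are averaged.
Each test lab's series is paired against the *reference laboratory's own
averaged readings*, not the noise-free design values: that is how the
shared curve is actually measured, and pairing against error-free truth
would attenuate the OLP slope. Default injected biases are of the size
estimated on the bundled table, with fixed biases capped below the lowest
dilution point so the inverse map stays positive.

*Cohorts.* Three groups (627 malignant / 583 benign / 299 healthy, the
published cohort sizes) with group-specific truncated-normal ages (18–70),
menopause probabilities (0.754/0.377/0.482) forced consistent with age
(never below 40, always above 55), truncated-normal creatinine, and
lognormal HE4 and CA125 moment-matched to the published group means/SDs
(e.g. malignant HE4 mean 474, SD 1207 — a log-SD ≈ 1.4 heavy tail). The
published malignant CA125 SD of 7.9 IU/mL is treated as a typo
(implausible against a mean of 610) and replaced by a dispersion of 1500.
A `menopause_separation` parameter (default 0.5 log-SDs, of the order of
the published menopause accuracy coefficient) makes malignant
post-menopausal HE4 higher, so the marker discriminates better in the
post-menopausal stratum — the qualitative sign the ROC regression must
recover. Raw HE4 is the hospital's inverse-bias transform of the true
reference-scale value, floored at a small positive limit where the linear
bias map would go non-positive (a linear calibration is only meaningful
within the assay's measuring range). Default hospital biases are identity
so the marker moments match their published targets; bias injection is an
explicit config choice in recovery experiments and in the default
`run_study` demonstration, which reuses the calibration sim's biases.

*What passing tests show — and don't.* Parameter recovery, AUC agreement
and coverage results on these cohorts validate the estimation machinery,
not the clinical conclusions: real cohorts have non-lognormal tails,
informative missingness, hospital case-mix differences and assay drifts
that the generator does not emulate, and the published cohort's numeric
AUCs and regression coefficients are not reproducible without the
undeposited data.

## Numerical conventions and problem sizes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; simulation tests are frozen to fixed seeds.
- Sample-size-style ceilings use exact integer arithmetic (`math.ceil`).
- Monte-Carlo problem sizes in the test suite (e.g. 2000/2000 binormal
  recovery, 100 coverage replicates of 150/150 cohorts with 200 bootstrap
  refits, 40 replicate pipeline-recovery runs) are chosen so each check
  has ~3 Monte-Carlo standard errors of headroom against its tolerance
  while the full suite stays fast.
- Slope recovery of a single 10-point duplicate calibration at a 10%
  platform CV has a sampling SD near 5%; per-laboratory recovery
  tolerances of ±0.05 are therefore asserted on means over replicate
  experiments, with a wide gross-error band on single runs.
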