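# Methods

`smokemr` implements a triangulated causal analysis of a composite smoking
exposure against incident chronic kidney disease (CKD stages 3–5), exercised
end-to-end on a synthetic biobank-style cohort with known ground truth.  This
note records the models, the defaults and why they were chosen, and what the
synthetic benchmark does and does not demonstrate.

## The exposure

The lifetime smoking index is

    I = (1 − 0.5^(dur/τ)) · 0.5^(tsc/τ) · ln(int + 1),

with duration `dur` and time since cessation `tsc` in years, intensity `int`
in cigarettes/day, and half-life τ = 18 years on both time axes.  The
logarithm is natural.  The index's defining worked example — 20/day for 15
years quit 17 years ago versus 60/day for 13 years quit 22 years ago — is
base-invariant (both profiles scale identically under a change of base), so
it cannot disambiguate the base; natural log follows the index's source
definition and both τ and the log base are exposed as parameters.  Never
smokers score exactly 0; a missing smoking status yields a missing index
(participants are excluded, not imputed at zero).

## The outcome

Incident CKD is ascertained from an enumerated diagnosis-code list (ICD-10
N18.0/.3/.4/.5/.8/.9, I12.0, I13.1, I13.2; ICD-9 585.9).  Matching is exact
on the normalized code — a bare `N18` does not qualify — because the clinical
definition enumerates specific stage codes.  Prevalent disease (first
qualifying code on or before baseline) excludes the participant; otherwise
the first post-baseline code defines the event time.  Cohort exclusions are
applied in a fixed order (prevalent disease, follow-up < 180 days, missing
exposure), each row counted once under the first matching rule, so exclusion
counts always reconcile with the retained count.

## The synthetic cohort

The generator encodes the data-generating assumptions the estimators rely
on, with one integer seed driving a single named generator (bit-identical
reruns).  Per configuration: SNP panel metadata (effect-allele frequencies
uniform on the configured range, allele labels) and the identity of any
pleiotropic SNPs are derived deterministically from the seed, so every
cohort drawn under a configuration shares the same genetic architecture.

* **Genotypes** are two independent allele draws per SNP — Hardy–Weinberg by
  construction.
* **Exposure.** A latent index `L = α_x + Σ β_i (G_i − 2p_i) + γ_U·U + ε`
  with U ~ N(0,1) the unmeasured confounder and ε normal.  The observed
  index is `X = max(L, 0)`; α_x is positioned so the zero mass equals the
  target never-smoker fraction (default 0.549, matching a 45.1% ever-smoker
  cohort).  Default per-allele effect 0.1 index units across 42 SNPs makes
  the combined polygenic score a strong instrument at desk scale (combined
  first-stage F in the hundreds, as in the strong-instrument setting the
  design assumes); the per-SNP noise SD default is 0.9 index units, which
  puts the ever-smoker median index near 0.9, close to the reported 1.07.
* **Smoking-field decomposition.** For ever smokers, intensity is lognormal
  (median ≈ 15/day) truncated to [1, 100]; time since cessation is 0 for
  current smokers (30% of ever smokers) and otherwise uniform on
  [1, 0.6·(age−16)]; duration then solves the index identity in closed form
  (the duration factor is an explicit exponential, monotone increasing, so
  the solution is unique).  Indices outside the attainable range for the
  sampled fields are clipped to it and the stored exposure updated, so
  re-applying the index formula to the emitted fields reproduces the stored
  exposure exactly for every participant; clip counts are warned.
* **Outcome.** A single exponential event time with log-hazard
  `log λ₀ + θX + δ_U·U + Σ c_j G_j` (c_j the planted direct pleiotropic
  effects) drives both the time-to-event and the binary flag
  (event before administrative censoring at 4,675 days), so the survival and
  logistic arms see mutually consistent data.  λ₀ is derived from the
  baseline logit α₀ so that null-case prevalence equals expit(α₀) exactly
  (default 3.9%).  At that incidence the log-odds and log-hazard scales
  agree to well under the estimators' standard errors, so the planted θ is
  the target of every estimator.
* **Covariates.** Age uniform 40–69, sex Bernoulli(0.455), 10 centres, 10
  standard-normal genetic PCs; U loads on BMI, diabetes and hypertension;
  the remaining lifestyle/socioeconomic fields are independent categoricals
  with realistic margins and missingness fractions — they exist so the
  baseline table and adjusted models have the structure they consume, not to
  model real lifestyles.  Small fractions of prevalent disease (2%), missing
  smoking fields (2%) and early dropout (1%) exercise the exclusion rules.

The default configuration is a **confounded null** (θ = 0, γ_U = 0.4,
δ_U = 0.5): no causal effect, but the confounder raises both exposure and
hazard — the regime in which observational and instrumental analyses
disagree, which is the pipeline's reference scenario.

What the generator does *not* emulate: linkage disequilibrium (an optional
user-supplied LD matrix feeds the clumping step instead), population
structure and relatedness, age-dependent smoking trajectories, questionnaire
skip patterns, and non-proportional hazards.  Passing benchmarks therefore
demonstrate the estimators' operating characteristics under their own
assumptions, not robustness to those real-data complications.

## Instruments

Selection keeps SNPs with exposure p < 5×10⁻⁸, optionally intersected with
an allowed-id list (the directly-genotyped restriction).  Greedy LD clumping
(rank by p, drop in-window SNPs with r² ≥ 0.0001 within 10,000 kb) breaks
p-value ties lexicographically on SNP id so output is invariant to row
order.  The polygenic score is the raw weighted risk-allele count; it is
deliberately unstandardized because the two-stage estimand is invariant to
instrument scaling (asserted in tests).  Missing dosages are mean-imputed at
2·eaf.  Instrument strength is reported as the squared t of the score in the
exposure regression (the single-combined-instrument F) plus incremental R².
The validity screen flags SNPs associated with any supplied confounder GWAS
at 5×10⁻⁸ and SNPs directly associated with the outcome at Bonferroni
0.05/M.

## One-sample MR

*2SLS with logistic second stage*: stage 1 regresses the index on the score
plus covariates (age, sex, centre, 10 PCs in both stages); stage 2 is a
logistic regression of the outcome on the stage-1 fitted values plus the
same covariates.  *Confidence intervals* come from a participant-level
nonparametric bootstrap (default 500 resamples, both stages refit per
resample, seeded); this is valid for both 2SLS and G-estimation without
plug-in variance approximations.  Intervals are percentile intervals and the
reported SE is the normalized IQR of the bootstrap draws: the instrumented
estimators are ratio-like and right-skewed, and a diagnostic study showed
the plain bootstrap SD overestimating the sampling SD by ~20% (occasional
extreme resamples), so normal intervals overcover; the percentile/robust-
spread pair restores near-nominal coverage.  An analytic stage-2 Wald
option exists for
replicate-level studies: under the null the stage-2 Wald test is exactly the
reduced-form instrument–outcome test and is asymptotically calibrated, and
at thousands of replicates the bootstrap is not the quantity under study.

*G-estimation*: the causal odds ratio is the root ψ of the structural-mean-
model estimating equation — the covariate-residualized instrument must be
uncorrelated with H(ψ) = expit(logit p̂ − ψX), the outcome with the exposure
effect removed on the logistic scale, where p̂ comes from a logistic
association model in (X, Z, covariates).  The root is bracketed by a grid
scan over [−10, 10] (the estimating function flattens as H saturates, so
endpoint signs alone can miss the root) and polished by Brent's method to
10⁻⁶.  G-estimation and 2SLS agree in the rare-outcome (collapsibility)
limit and diverge as prevalence grows; both behaviors are tested.

*Nonlinear (LACE) analysis*: participants are split into three equal-size
strata on the residual of the exposure given instrument and covariates (not
on the exposure itself, which would induce collider bias; ties keep stable
sort order).  Each stratum's localized average causal effect is the ratio of
the reduced-form logistic coefficient to the first-stage coefficient, with a
full delta-method SE (both stages' sampling error).  Nonlinearity tests:
(i) the quadratic term of a fixed-effect meta-regression of stratum
estimates on stratum mean exposure — with three strata the fit is saturated
and inference comes from the known per-stratum variances; (ii) Cochran's Q
across strata.  Both calibrate at the nominal 5% under linear truth.

*Subgroups* follow the standard layout (age below/at-or-above the cohort
median, sex, diabetes, hypertension, BMI 25 cut), dropping the stratifier
from the covariate list; undersized (<100 rows) or separated subgroups are
skipped with a warning, as tiny event counts make the second stage
inestimable.  *Leave-one-out* rebuilds the score without each SNP in turn;
*sensitivity scores* drop confounder- or outcome-flagged SNPs, with a second
variant additionally adjusting both stages for BMI/diabetes/hypertension.

*Power* uses the normal approximation
`power = Φ(|β|·√(n·r²·f(1−f)) − z_{1−α/2})` (r² the instrument's share of
exposure variance, f the case fraction), verified against simulated
rejection rates within ±7 points.  This is the package's own documented
formula, not a reimplementation of any particular online calculator.

## Two-sample MR

Harmonization inner-joins on SNP id, flips swapped outcome records, orients
palindromic SNPs by allele frequency when both frequencies are outside the
0.42–0.58 ambiguity window (dropped otherwise), and drops irreconcilable
allele pairs with a log entry.  Estimators, all on harmonized tables:

* **IVW (fixed effect)** — weighted least squares through the origin with
  weights se_out⁻²; the main method.  First-order weights only.
* **Maximum likelihood** — bivariate normal measurement model with per-SNP
  latent exposure effects and a common slope, profiled and optimized from
  the IVW start; SE from the observed information.
* **MR-Egger** — WLS with intercept after orienting exposure effects
  non-negative (the method's identifying convention); residual-scale
  estimated; intercept and slope tested on M−2 df.
* **Weighted median** — interpolated ratio at cumulative weight 0.5; SE by
  parametric bootstrap from the stated errors (1,000 draws, seeded).
* **Weighted mode** — peak of the inverse-variance-weighted normal-kernel
  density of the ratios, bandwidth = φ × 0.9·min(sd, MAD)·M^(−1/5)
  (modified Silverman, φ = 1 default); degenerate ratios fall back to the
  exact mode with a warning.

Validity battery: Cochran's Q (χ² on M−1 df), the Egger intercept test, and
MR-PRESSO — observed weighted RSS against leave-one-out IVW slopes, null
distribution by simulating outcome effects from their fitted means and
stated errors (1,000 draws), global p with the plus-one rule, per-SNP
outlier p-values Bonferroni-flagged at 0.05/M.

## Observational arm

Cox proportional-hazards models (Efron tie handling, convergence tightened
to make the estimate agree with direct partial-likelihood maximization to
10⁻⁶) for ever-vs-never smoking and per-unit index, unadjusted and adjusted.
Categorical covariates encode missingness as its own level, mirroring the
baseline table; rows missing continuous covariates are dropped with a logged
count.

The exposure–response curve is a P-spline on the Cox partial likelihood: a
cubic B-spline basis (10 functions, interior knots at quantiles) with a
second-difference penalty, fitted by Newton iteration with step-halving and
a log-sum-exp–stabilized Efron likelihood.  The penalty is tuned by
bisection on its log scale until the effective degrees of freedom
trace((H + λP)⁻¹H) match the target within 0.05 — "2 degrees of freedom" is
treated as a target, not a basis size — with df 3 and 4 as sensitivity
variants.  The curve is referenced to the 1st percentile of the exposure
(data trimmed to the 1–99% range), with a pointwise 95% band from the
penalized information matrix.  A tiny information-scaled ridge keeps the
constant direction of the basis (which the partial likelihood cannot see)
numerically invertible without affecting the fit.

## Pipeline and reproducibility

One master seed fans out to per-stage seeds by fixed offsets; the manifest
records the configuration snapshot and hash, seeds, per-stage row counts and
every emitted file.  All tables are tab-separated text and parse back by the
module that produced them.  The comparative report reduces the run to one
verdict line (e.g. "observational association present; MR null").

## Problem sizes

Benchmarks are sized for single-CPU desk-scale runs: calibration of the
2SLS/IVW tests uses 2,000 replicates at n = 10,000 with 42 SNPs;
Egger/MR-PRESSO calibration 300 replicates; coverage at a planted effect
300 (summary-level) and 100 (individual-level, 200 bootstrap resamples)
replicates; LACE calibration 200 replicates; the confounded-null discrepancy
50 replicates at n = 20,000; the weighted-median breakdown study 100
replicates with summary cohorts of 50,000 and pleiotropy planted on the
weaker 40% of instruments (see the benchmark's docstring for why weight
share, not SNP count, is the operative quantity).  The end-to-end
reproduction run (`scripts/acceptance.py`) uses 300 bootstrap resamples for
the pipeline's one-sample intervals.  The default pipeline cohort is 20,000
participants with summary-statistics cohorts of 50,000 — far below biobank
scale, so instrument effect sizes are correspondingly larger than real GWAS
hits; the benchmark validates estimator behavior, not real-world effect
magnitudes.

## Known limitations

Two-sample bootstrap SEs (weighted median/mode) are plain bootstrap SDs with
normal intervals; only the one-sample estimators use percentile intervals.
MR-PRESSO implements the global and outlier tests but not the
distortion test.  IVW is fixed-effect only.  The spline's basis and penalty
family are this package's own choice; only the properties documented above
(effective df, reference normalization, linear-truth recovery) are
guaranteed.  Subgroup estimates inherit the instability of small event
counts, as their wide intervals make plain.
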