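# Methods

This note records the models implemented in `cohortmr`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Cohort arm

**Outcome model.** Incident stroke is a single end-of-follow-up binary;
the association model is maximum-likelihood logistic regression (no
time-to-event structure — the emulated design reports odds ratios despite
follow-up, and so do we). Fits use IRLS (statsmodels GLM, binomial family)
with deviance-based convergence: a covariate level with zero events gets a
divergent coefficient and an effectively infinite upper confidence limit
rather than a spurious failure, matching R `glm` behaviour. Complete
separation of the design is escalated to a `SeparationError`. All
confidence intervals are Wald, `exp(β̂ ± z₀.₉₇₅·SE)` — profile-likelihood
intervals are asymmetric on the log scale and would not match the
symmetric-on-log-OR convention of this literature.

**Exposure coding.** Quartile cutpoints are the empirical 25/50/75
percentiles (linear interpolation between order statistics — the numpy
default and the dominant convention). Ties at a cutpoint go to the *lower*
quartile, i.e. intervals are `(−∞,c₂₅], (c₂₅,c₅₀], (c₅₀,c₇₅], (c₇₅,∞)`;
this is deterministic and order-independent. Exposure with no variation
(degenerate cutpoints) is an error, not a silent 1-quartile fit. The
log-continuous coding uses the natural log, accompanied by a one-sample
Kolmogorov–Smirnov report of raw vs logged values against a normal law
with matched mean/SD (parameters estimated from the data; the report is a
descriptive skewness diagnostic, not a formal test with Lilliefors
correction).

**Adjustment sets.** `model1` = age group (<65, 65–84, ≥85) + sex;
`model2` adds residence, education, marital status, smoking, current
drinking, BMI group, hypertension, diabetes, triglyceride, non-HDL
cholesterol and glucose; sensitivity variants add hs-CRP or fasting
status. References are the first listed level of each categorical.

**Missing covariates.** The main policy converts categorical missingness
into an explicit `missing` level. The analogous device does not exist for
continuous covariates, so they are mean-imputed with an added missingness
indicator — the standard "missing-indicator" extension; complete-case
deletion is available as the alternative policy, and the choice is logged
in the fit metadata.

**Subgroups and interaction.** Stratifiers are dichotomised as commonly
tabulated: age at 65 (the boundary value joins the older stratum by
default; configurable), obesity as BMI ≥ 28, smoking as never vs
current/former. Each stratum refits `model2` minus the stratifying
covariate. Interaction p-values are reported per quartile contrast (Wald
test of each quartile×stratum product term in a pooled model), not as one
global 3-df test, because the per-contrast layout is what subgroup tables
in this literature print. Strata with zero events are flagged and excluded.

**Dose–response.** Restricted cubic spline with k = 3 knots at the
10/50/90th exposure percentiles, Harrell normalization (division by
(t₃−t₁)²) so the nonlinear coefficient is scale-stable. The curve is
OR(x) = exp(η(x) − η(x_ref)) with x_ref the 10th percentile; pointwise CIs
come from the delta method on the contrast vector, so OR(x_ref) ≡ 1 with a
zero-width band. The grid is 200 evenly spaced points between the 1st and
99th percentiles to avoid tail extrapolation artefacts; fewer than 50
events attaches an instability warning. Whether the curve is adjusted with
`model1` or `model2` is a switch (default `model2`).

**Multiple imputation.** m = 5 imputed datasets ("five iterations" in
applied writing almost always denotes the number of imputations, not MCMC
sweeps; the sweep count is a separate internal parameter, default 10 per
independent chain). Chained-equation updates: continuous targets by
Bayesian linear-regression draws (residual variance from a scaled inverse
chi-square, coefficients from their normal posterior, plus residual
noise); categorical targets by multinomial logistic fits sampled from
predicted class probabilities. Only covariates are imputed — outcome and
exposure must be complete; a column over 90% missing is refused. Pooling
uses Rubin's rules with the Barnard–Rubin small-sample degrees of freedom
(valid at m = 5 with moderate missing information; the old large-sample df
is anti-conservative there), taking the complete-data df from the analysis
model. When between-imputation variance is exactly zero the df is infinite
and the pooled CI is the normal-theory one.

**Discrimination.** AUCs use the Mann–Whitney estimator with the ½-tie
convention; the paired DeLong test uses midrank placement values and a
normal reference. By default the compared scores are the *raw* biomarker
values (cystatin C vs creatinine) — the comparison is between indicators,
not fitted risk models; a model-score comparison can be run by passing any
score columns. Identical scores give p = 1 by construction; zero variance
with a nonzero difference is flagged degenerate.

## MR arm

**Selection and clumping.** Instruments require p strictly below 5×10⁻⁸.
Clumping is greedy: visit SNPs by ascending p (stable for ties), accept
unless a previously accepted SNP on the same chromosome lies within the
10,000-kb window *and* has r² ≥ 0.001 with it. LD pairs absent from the
reference are treated as r² = 0; the chromosome/window test is applied
before the r² lookup, so a spurious cross-chromosome r² entry cannot prune
anything.

**Harmonization.** Outcome records are aligned to the exposure's effect
allele: matching alleles pass; swapped effect/other alleles flip the beta
sign and eaf; strand-complement records are complemented and re-compared.
Palindromic (A/T, C/G) SNPs are label-aligned first and then checked by
allele frequency: if min(eaf, 1−eaf) ≥ 0.42 in either study the frequency
cannot resolve the strand and the SNP is dropped; a discordant frequency
after label alignment is read as a strand flip. The 0.42 limit is the
conventional ambiguity threshold in two-sample MR tooling. Every SNP
carries an `action_taken` audit label.

**Estimators.** The Wald ratio uses the second-order delta expansion by
default (`sqrt(se_out²/βx² + βy²se_x²/βx⁴)`) — conservative relative to
the first-order `se_out/|βx|`, which is available by flag. Random-effects
IVW uses multiplicative overdispersion: pooled SE scaled by
`sqrt(max(1, Q/(n−1)))`, the dominant convention in two-sample MR software
and stable at large instrument counts (an additive between-SNP variance
component is deliberately not estimated). MR-Egger pre-orients every
instrument to βx > 0 (its formulation requires it), weights by 1/se_out²,
applies the same floored overdispersion with n−2 df, and uses t reference
distributions.

**MR-PRESSO.** The global test refers the observed weighted RSS of
leave-one-out IVW predictions to `n_sim = 1000` parametric simulations
under the no-pleiotropy model, with the (1+#exceed)/(1+n_sim) p estimator.
The per-SNP outlier test summarises each SNP's simulated null as a scaled
χ²(1) (scale = mean simulated RSS term) and compares tail probabilities to
the Bonferroni threshold α/n. The smooth tail matters: with 223 SNPs the
Bonferroni threshold is ≈2×10⁻⁴, below the 1/1001 granularity of an
empirical rank, which would make the test either blind or dominated by
rank-zero noise. Raw and corrected estimates inside PRESSO use first-order
(1/se_out², regression-scale) weights — the same weighting as the RSS
machinery; letting an outlier's own inflated outcome effect deflate its
weight (second-order) would be inconsistent with the simulated null. The
distortion test compares the observed estimate shift after outlier removal
with shifts from removing 1000 random same-size subsets. All simulation
counts are explicit, seeded parameters.

## Synthetic data

`generate_cohort` draws log-normal cystatin C (default μ = −0.0305,
σ = 0.198 on the log scale, placing the empirical quartile cuts near
0.85/0.97/1.11 mg/L), an outcome whose logit is a per-quartile baseline
(default targets 7.9/9.4/9.4/13.2%, ≈10% overall at n = 6,501) plus
optional covariate and quartile×covariate effects, and the usual covariate
roster with marginals matching the emulated cohort's descriptive profile.
Age and serum creatinine are correlated with the exposure (renal function
declines with age; both markers share the filtration signal) — this is
what makes the marker-discrimination comparison meaningful. All other
covariates are independent given the exposure quartile: the emulated study
reports only marginals, so no cross-covariate correlation is claimed, and
recovery tests stay interpretable. Missingness is injected MCAR per
covariate — the simplest mechanism under which both the missing-category
and the imputation analyses are unbiased. Continuous effects are applied
to centred values so the quartile baselines stay calibrated.

`generate_gwas_pair` draws per-SNP exposure effects uniform on
(0.04, 0.12) per SD (all positive: the effect allele is oriented
exposure-increasing, the convention under which "directional" pleiotropy
is meaningful), MAF uniform on (0.10, 0.50), exposure SE
`1/sqrt(2·maf·(1−maf)·N)` with N = 363,228, outcome SE from the effective
case/control sample size (40,585 / 406,111). The default true causal
effect is ln(1.114) per SD. Pleiotropy modes: none, balanced
(mean-zero), directional (mean 0.02); planted outliers add directional
pleiotropy of 12–16× the outcome SE (the ≥10× regime where an outlier test
should fire). Harmonization is exercised by storing 25% of outcome records
effect/other-swapped and 10% strand-complemented, with 10% palindromic
SNPs whose eaf is kept below 0.35 so frequency alignment is informative.
Independent instruments are spaced >10 Mb apart across 22 chromosomes with
background r² < 10⁻⁴; optional proxy clusters add correlated, slightly
weaker neighbours that clumping must remove. Both generators are pure
functions of their config and emit a JSON truth sidecar (quartile log-ORs,
covariate effects, causal effect, outlier ids, per-SNP pleiotropy).

**What the generators do not emulate** — and hence what passing tests do
not show about real data: no survey design or sampling weights, no
genuine confounding structure between covariates, no MNAR missingness, no
LD-induced correlation among retained instruments, no winner's-curse
selection of instruments from the same sample, and summary statistics are
drawn directly rather than from individual-level genotypes.

## Reproducibility and problem sizes

One global seed spawns per-stage substreams keyed by stage *name* (SHA-256
of the name XOR the seed), so adding or removing a pipeline stage never
reshuffles another stage's draws; manifests record per-stage seeds and
output checksums. The test suite and the acceptance script size their
Monte-Carlo loops as 100-replicate coverage checks (cohort recovery, IVW
coverage, PRESSO planted-truth), 400-replicate null-calibration checks
(PRESSO global test, at 50 instruments under the null), 1000-replicate
checks for cheap scalar statistics (DeLong type-I error, Rubin CI
coverage) and 10⁶ draws for the delta-method SE — sizes chosen to make the
binomial noise of each check small relative to its acceptance band while
keeping a full run in the low minutes on one CPU.

## Known limitations

* Logistic ORs ignore follow-up time; with ~10% cumulative incidence they
  overstate risk ratios slightly.
* The missing-indicator device for continuous covariates is known to be
  biased under MAR-on-covariates; it is provided for fidelity to the
  emulated analysis, with multiple imputation as the principled
  alternative.
* The K–S normality report estimates parameters from the data, so its
  p-values are conservative as an absolute test; only the raw-vs-logged
  comparison is meant to be interpreted.
* MR-PRESSO's corrected estimate removes flagged SNPs and re-pools; with
  few, mildly pleiotropic outliers the raw-estimate bias can be comparable
  to the corrected estimate's sampling noise, in which case removal is a
  wash on mean-squared-error grounds even when detection is perfect.
* Weighted-median/mode estimators, multivariable MR, Steiger filtering and
  survival modelling are out of scope.
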