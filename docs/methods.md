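# Methods

This note documents the models implemented in `facohort`, the assumptions
behind the synthetic-cohort generator, the numerical choices made where the
design was genuinely open, and the limits of what the tests demonstrate.

## Study design being modelled

A birth cohort of 2,940 infants with questionnaire data on housing
characteristics and LRI outcomes in the first year of life. Indoor
formaldehyde (FA) was measured with 7-day passive samplers four times during
the year in the dwellings of 196 randomly selected infants (missing by
design, hence missing completely at random); everyone else's exposure must be
predicted. The analysis is two-stage: an exposure model fitted on the
measured subsample assigns FA to the whole cohort, then outcome regressions
estimate adjusted FA–LRI associations. A fully Bayesian joint model treats
the unmeasured log-FA values as latent and re-estimates the association with
imputation uncertainty propagated.

## Exposure side

**Annual level.** Arithmetic mean of the per-season levels in µg/m³. A
dwelling needs at least `min_seasons` (default 3 of 4) seasons, otherwise its
annual level is undefined and the dwelling is excluded; the default mirrors a
measured subsample in which roughly 85–90 % of investigated dwellings retain
a defined annual level. Below-quantification-limit values (LOQ 2.4 µg/m³) are
substituted by LOQ/2 by default (`half_loq`); `loq` and `as_reported` are
available. The substitution rule is an implementation choice — at the
generator's level distribution (median ≈ 19.5 µg/m³) below-LOQ values are
essentially absent.

**Predictive models.** Natural-log annual levels are modelled by OLS ("log"
is taken as the natural logarithm); the "high" class (above the observed
median) by maximum-likelihood logistic regression; tertile classes by a
3-category multinomial logit with the lowest tertile as reference. Candidate
predictors pass a univariate screen (group F/LR test, p ≤ 0.20, forced-in
set supported). The duration-of-window-opening term is always adjusted for
season of declaration (season dummies accompany it into the design). AIC
model selection is available as exhaustive subset search up to 12 predictor
groups and backward elimination beyond; ties break toward fewer parameters,
then lexicographic predictor order. Wald standard errors, 95 % CIs
(z = 1.96) and two-sided p-values are used throughout; odds ratios are
`exp(coefficient)` by construction.

**Diagnostics.** Variance inflation factors per design column; the
Hosmer–Lemeshow χ² over deciles of fitted risk, statistic
Σ (O−E)²/(E(1−E/n_g)) with g−2 degrees of freedom, ties kept in one group and
degenerate groups merged; confusion-matrix rates with "high FA" as the
positive class; AUC in the Mann–Whitney form (ties count ½). Linear-model
predictions are classified against the *observed* median before comparison
with observed classes, so the linear and logistic models are evaluated on the
same footing.

**Cohort assignment.** Per-dwelling levels are `exp(x'γ̂)` (the conditional
median under log-normality — chosen over the conditional mean
`exp(x'γ̂ + σ̂²/2)` because classes are defined against the observed median,
which is preserved by monotone transforms). A subject's annual level is the
residence-time-weighted mean over the dwellings occupied during the year
(`longest`-dwelling assignment available as an option); the subject is "high
all year" only if every occupied dwelling is predicted high. Class cut-points
are frozen from the measured sample and never re-estimated on predictions.

## Health side

Binary logistic regression of any-LRI, and a multinomial logit of
never/non-wheezy/wheezy LRI with never-LRI as the reference stratum, adjusted
for covariates passing a univariate screen at p ≤ 0.20 plus forced-in
confounders (socio-economic status by default). Exposure enters continuously
in µg/m³ by default (median or tertile class coding available). The FA effect
is reported per interquartile-range increase: `OR = exp(β·w)` with Wald CI
`exp((β ± 1.96·se)·w)`; by default `w` is the IQR of the assigned cohort
exposure (logged), and any fixed width can be supplied for comparability.
Rows with missing covariates are dropped (complete-case) with the count
reported.

Because assigned exposure is a prediction, its between-subject spread is
compressed relative to the true exposure, and the per-assigned-IQR OR is
attenuated toward 1 relative to the generating per-IQR effect — verified as a
property test. This regression-dilution behaviour motivates the Bayesian
model.

## MCAR diagnostics

Each exposure predictor is tested against the measurement indicator R:
χ² independence tests for categorical predictors (Fisher's exact for sparse
2×2 tables, a seeded Monte-Carlo permutation test for larger sparse tables),
Welch t-tests for continuous ones; Bonferroni adjustment over the m
predictors tested. The global test is a likelihood-ratio χ² comparing
logistic `R ~ all predictors` with the intercept-only model (df = number of
dummy-coded columns; constant columns are dropped). Both tests are
type-I-calibrated on null replicates in the test suite.

## Fully Bayesian joint model

One posterior over exposure-model parameters (γ, σ), latent log-FA for every
unmeasured dwelling, and outcome parameters (θ, β):

- exposure: `log FA_d ~ N(x_d'γ, σ²)`; for measured dwellings log FA is fixed
  at the log observed annual mean (no extra measurement-error term);
- outcome: binary `logit P(LRI_i) = z_i'θ + β·FA_i` or the three-category
  multinomial analogue with stratum-specific (θ_k, β_k); subject exposure is
  the residence-weighted `Σ_j w_ij exp(log FA_j)` in µg/m³, so the latent
  *level* (not its log) enters the outcome model;
- priors: N(0, 10²) on all regression coefficients, Half-Normal(0, 5²) on σ
  (configurable).

Sampler (Metropolis-within-Gibbs, single chain, default 10,000 iterations
with 1,000 burn-in):

1. γ — exact conjugate Gibbs draw given all current log-FA values.
2. σ — random-walk on log σ proposed *jointly* with a rescaling of the latent
   residuals `f_l ← μ + (σ'/σ)(f_l − μ)`; the latent prior terms cancel
   against the Jacobian, so σ is informed by the observed dwellings and the
   outcome likelihood. This removes the severe σ–latent autocorrelation a
   naive conditional update exhibits when >90 % of dwellings are latent.
3. Latent log-FA — group-wise vectorised independence proposals from the
   exposure prior N(x'γ, σ); the accept ratio reduces to the per-dwelling
   outcome-likelihood ratio (~95 % acceptance, global moves). Dwellings are
   greedily grouped so no two dwellings in one vectorised block share a
   subject.
4. (θ, β) — a Laplace-approximation independence proposal (ML fit refreshed
   every 50 sweeps during burn-in, covariance inflated 1.4×, frozen at
   burn-in end), followed by a random-walk Metropolis step with the ML
   covariance shape (scale adapted to 23.4 % acceptance during burn-in) and a
   single-coordinate step on each β.

All adaptation stops at the end of burn-in, so the retained chain targets the
exact posterior. Everything is deterministic given the seed. Reported per
parameter: posterior mean, SD, 2.5/97.5 percentiles, ESS (via `arviz`), lag-k
autocorrelations and a Geweke z-score (batch-means long-run variance);
parameters with ESS < 100 or |z| > 2 are flagged. Latent log-FA draws for
individual dwellings can be retained (`track_latent`) — their posterior
concentrates around x'γ with spread at most the prior-predictive SD.

With only ~7 % of dwellings measured, the posterior of the wheezy-LRI FA
effect is a genuinely noisy quantity: across synthetic cohort replicates its
posterior mean scatters widely (without systematic bias), and single-dataset
effective sample sizes of a few hundred per 10,000 iterations are typical.
The binary-outcome credible interval attains near-nominal coverage of the
generating per-IQR OR in the replicate tests.

## Synthetic-cohort generator

The generator emulates the study conditions; its defaults are fixed, not
tuning knobs.

- **Dwellings** (2,940 + extra dwellings for movers): predictors drawn
  independently from the published marginal frequencies (no joint
  distribution is published; a correlation extension would slot into the
  config). Window-opening hours are Gamma(2, 1.5) (mean 3 h/day). The split
  of "material present" into ≥1-year / <1-year age levels is not published;
  defaults place most material in the older level (e.g. particle board
  0.334/0.550/0.116 for none/old/new).
- **True exposure**: log FA = 2.2237 + Σ published coefficients + N(0, 0.369).
  Intercept and residual SD were calibrated once numerically (n = 60,000) so
  the *observed* annual level has median ≈ 19.5 µg/m³ and IQR ≈ 14.4–26.8,
  then frozen.
- **Measurements**: per season, log level = true log FA + seasonal offset +
  N(0, 0.15). Offsets (winter −0.15, spring −0.05, summer +0.25, autumn
  −0.05) sum to zero and encode the hotter-season elevation; their magnitude
  and the 0.15 sampler noise are free parameters (no published values exist).
  Each season is independently missing with probability 0.15, so ~85–90 % of
  measured dwellings keep a ≥3-season annual level.
- **Subsample**: 196 subjects drawn uniformly without replacement; all their
  dwellings are measured — MCAR by construction. Movers (probability 0.103)
  occupy two dwellings with a uniform split point.
- **Outcomes**: 3-category multinomial logit on the covariates (published
  adjusted ORs; the binary-model ORs stand in for the unpublished
  non-wheezy-stratum ORs; SES effects are zero) plus the FA level. The wheezy
  stratum's FA effect is log(1.41)/12.4 per µg/m³; the non-wheezy stratum's
  is log(1.32²/1.41)/12.4 so the collapsed binary model has per-IQR OR ≈ 1.32.
  Intercepts were calibrated once (n = 60,000 root-find) to incidences 45.8 %
  (any LRI) and 22.3 % (wheezy), then frozen at (−1.731, −2.272).
- **RNG**: named independent streams (dwellings / measurements / subjects /
  outcomes) derived from the seed, so changing e.g. the FA effect perturbs
  only the outcome draws.

What the generator does *not* emulate: predictor correlations, questionnaire
nonresponse, within-year covariate changes other than residence, seasonal
confounding between declaration season and true exposure, and any
mis-specification of the exposure or outcome link functions. Passing tests
therefore show internal consistency of the method under its own assumptions,
not robustness to real-data violations of them.

## Problem sizes used in the test suite

Stochastic checks are run at sizes chosen to keep the full suite fast while
retaining power: exposure-model recovery uses 200 replicates of 174 measured
dwellings; the attenuation/coverage study uses 20 cohorts of 1,500 subjects
with 100 measured dwellings and 2,000 MCMC iterations; calibration checks use
500 null replicates. The acceptance script runs a single cohort at the full
study scale (2,940 / 196) with the default 10,000-iteration chains.

## Known limitations

- Single-chain default (a multi-chain R-hat workflow would strengthen
  convergence assessment; Geweke + ESS + trace thirds are what's built in).
- The joint model treats the observed annual mean as exact log-FA; a
  measurement-error term for the observed dwellings would be a natural
  extension.
- The multinomial joint model's stratum effects mix more slowly than the
  binary model's; for headline wheezy-LRI posteriors, longer chains
  (≥30,000) are advisable.
- Whether the tertile exposure model should be ordinal rather than
  multinomial is ambiguous in the design being reproduced; multinomial is
  implemented.
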