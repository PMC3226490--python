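# facohort

Two-stage exposure modelling for indoor formaldehyde (FA) in a birth cohort,
with adjusted lower-respiratory-infection (LRI) association models and a fully
Bayesian joint-imputation sensitivity analysis.

## The problem

Measuring an indoor air pollutant in every home of a large birth cohort is
infeasible; studies therefore measure a random subsample of dwellings and
predict exposure for everyone else from questionnaire-reported housing
characteristics. `facohort` implements that complete analysis chain for
formaldehyde and infant LRI, for epidemiologists and biostatisticians who want
a testable, reproducible implementation of the design:

1. **Annual exposure** per dwelling: the arithmetic mean of seasonal 7-day FA
   measurements (µg/m³), requiring a configurable minimum number of seasons.
2. **Predictive exposure models** fitted on the measured subsample:
   - linear: `log FA_d = x_d'γ + ε_d`, `ε_d ~ N(0, σ²)` (FA is log-normal),
   - logistic: `logit P(FA_d > median) = x_d'γ*`,
   - multinomial for tertile classes,
   with univariate screening at p ≤ 0.20, VIF collinearity checks, AIC
   selection, Hosmer–Lemeshow calibration, and discrimination diagnostics
   (sensitivity, specificity, PPV, NPV, accuracy, Mann–Whitney AUC).
3. **Cohort assignment**: per-dwelling predictions, residence-time-weighted
   over moves; classes frozen at the measured sample's median/tertile cuts.
4. **Health models**: binary logistic for any LRI, and a three-level
   multinomial logit (never LRI / non-wheezy LRI / wheezy LRI, never-LRI
   reference), adjusted for screened covariates; the FA effect is reported as
   an odds ratio per interquartile-range increase, `OR = exp(β·IQR)`.
5. **Sensitivity analysis**: MCAR diagnostics (per-predictor χ²/t tests with
   Bonferroni correction, global likelihood-ratio test of `R ~ predictors`),
   then a fully Bayesian joint model sampled by Metropolis-within-Gibbs:

   ```
   log FA_d ~ N(x_d'γ, σ²)          observed for measured dwellings, latent otherwise
   logit P(LRI_i) = z_i'θ + β·FA_i   FA_i = Σ_j w_ij exp(log FA_j)  (binary form)
   ```

   with N(0, 10²) priors on coefficients and Half-Normal(0, 5²) on σ, so
   imputation uncertainty for the ~93 % unmeasured dwellings propagates into
   the posterior of β.

Because regressing outcomes on *predicted* exposure attenuates the per-IQR OR
toward 1 (regression dilution), the package's tests demonstrate the
attenuation on synthetic cohorts and show that the joint Bayesian model
restores nominal-coverage inference.

A bundled synthetic-cohort generator (`facohort.synth`) reproduces the study
conditions — 2,940 infants, 196 measured dwellings, published predictor
frequencies, exposure coefficients and outcome odds ratios, annual FA median
19.5 µg/m³ with IQR 14.4–26.8 — so every stage is testable without any data
download.

## Worked example

```python
from facohort.config import SynthConfig
from facohort.exposure import (annual_means, assign_cohort_exposure,
                               fit_linear_exposure_model, univariate_screen)
from facohort.health import covariate_screen, fit_binary_lri
from facohort.synth import make_cohort

cfg = SynthConfig(seed=7)                      # 2,940 subjects, 196 measured
dwellings, measurements, subjects, _ = make_cohort(cfg)

ann = annual_means(measurements, min_seasons=3)
screen = univariate_screen(ann, dwellings)
fit = fit_linear_exposure_model(ann, dwellings, screen["candidates"])
expo = assign_cohort_exposure(subjects, dwellings, fit)

res = fit_binary_lri(subjects, expo.set_index("subject_id")["annual_level"],
                     covariate_screen(subjects)["candidates"])
```

printed quantities (seed 7):

```
dwellings with a defined annual FA level: 180
median annual FA: 19.4 ug/m3
particle board (<1 yr) coefficient on log FA: 0.45 (SE 0.10)
in-sample classification accuracy: 71.1%
adjusted LRI OR per IQR (7.7 ug/m3) of assigned FA: 1.06 (95% CI 0.95, 1.19)
```

The exposure model recovers the generating particle-board effect (0.42) within
one standard error and classifies ~70 % of dwellings correctly. The naive
two-stage OR per IQR of *assigned* exposure is attenuated toward 1 relative to
the generating per-IQR OR of 1.32 — predicted exposure compresses the true
between-dwelling variation — which is exactly why the Bayesian joint model
exists: run `facohort.bayes.fit_joint_bayes` (or the `bayes` CLI command) to
obtain the posterior per-IQR OR with a 95 % credibility interval.

The same pipeline is scriptable from a shell:

```bash
facohort synth --seed 7 --out demo/
facohort validate --in demo/
facohort run-all --seed 7 --out demo/
```

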