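# nutrilcm

Gold-standard-free comparison of three malnutrition diagnostics — PG-SGA,
the ESPEN (2015) consensus criteria, and the GLIM criteria — in
colorectal-cancer cohorts, via a Bayesian latent class model, with
rule-pathway attribution of diagnostic discordance and survival
stratification. The patient-level oncology registry this kind of analysis
is run on is not public, so the package ships a synthetic-cohort generator
that reproduces the statistical structure of such a cohort (n ≈ 3,182,
~58.5% aged ≥65, ~59.7% male) and every stage is fully exercisable —
and tested — without any data download.

## Who this is for

Clinical-nutrition and biostatistics researchers who need to (a) apply the
three instruments' diagnostic rules reproducibly, (b) estimate each
instrument's sensitivity and specificity when *no* reference standard
exists, and (c) relate the resulting nutritional classifications to
overall survival.

## The model

With K = 3 binary tests applied to one population, true malnutrition
status is treated as a latent Bernoulli(π) class. Conditional on the
class, test results are independent, with per-test sensitivity Se_k and
specificity Sp_k, so an observed result pattern y ∈ {0,1}³ has probability

    P(y) = π · Π_k Se_k^{y_k} (1−Se_k)^{1−y_k}
         + (1−π) · Π_k (1−Sp_k)^{y_k} Sp_k^{1−y_k}.

The 2³−1 = 7 free cells exactly match the 7 parameters (π, Se₁..₃,
Sp₁..₃): the model is just-identified and flat Beta(1,1) priors suffice.
Fitting is by data-augmentation Gibbs sampling — all full conditionals are
conjugate (Binomial latent diseased counts per pattern, Beta updates for π
and each Se/Sp) — with 3 chains × 20,000 iterations (5,000 burn-in) by
default, equal-tailed 95% credible intervals, Gelman–Rubin R̂ diagnostics,
and a post-hoc orientation constraint Σ_k(Se_k+Sp_k) > K that resolves the
two-class mirror (label-switching) non-identifiability.

Around the model sit deterministic rule engines for the three instruments
(every published threshold implemented literally and pinned by boundary
tests), a discordance module that attributes each ESPEN⁺/GLIM⁻ patient to
the specific ESPEN clause responsible (the BMI 18.5–<20 band under age 70,
the “>10% at any time” weight-loss clause, low FFMI, or low BMI alone),
and from-first-principles survival machinery: Kaplan–Meier with median
survival, the log-rank test for ≥2 groups, and Cox proportional hazards by
damped Newton–Raphson on the partial likelihood (Efron tie correction by
default), cross-validated against `lifelines` in the test suite.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_diagnose.py
python analysis/03_fit_latent_class.py --seed 1
```

The simulation step prints the cohort marginals, the diagnosis step the
per-tool prevalence:

```
diagnosed 3182 patients
  PGSGA: 793/3182 malnourished (24.9%)
  ESPEN: 1112/3182 malnourished (34.9%)
  GLIM: 1060/3182 malnourished (33.3%)
```

ESPEN diagnoses malnutrition more often than the other two tools because
its thresholds are more inclusive — the discordance driver
(`analysis/04_discrepancy.py`) attributes each ESPEN-only diagnosis to the
clause responsible. The latent class fit then estimates the accuracy of
all three instruments *without* declaring any of them the reference:

```
posterior summaries (mean, 95% CrI):
  prevalence: 0.33 (0.31-0.35)
  se_PGSGA: 0.61 (0.58-0.64)
  ...
max R-hat: 1.0004 (converged)
```

(The mechanistic cohort violates conditional independence by design —
its tests share covariates — so these estimates differ from the
generator's nominal accuracies; `analysis/06_operating_characteristics.py`
shows that on cohorts satisfying the model's assumption the fit recovers
the truth with nominal coverage.) Finally `analysis/05_survival.py` prints
per-tool log-rank tests and Cox hazard ratios, e.g.

```
  GLIM: log-rank chi2=30.82 (df=2, p=2.028e-07)
    glim_moderate: HR 1.16 (1.03-1.30), p=0.01282
    glim_severe: HR 1.62 (1.36-1.93), p=1.114e-07
```

i.e. severity-graded malnutrition carries a graded survival penalty, with
the generator's true hazard ratios (1.29 moderate, 1.50 severe) inside the
Wald intervals.

The same stages are available as a CLI (`nutrilcm simulate | impute |
diagnose | crossclass | fit-lcm | discrepancy | survival | run-all`).

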