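# Methods

## Problem setting

Three instruments diagnose malnutrition in oncology cohorts — PG-SGA (an
additive questionnaire/examination score), the ESPEN 2015 consensus rules,
and the GLIM phenotypic + etiologic framework — and they disagree
substantially in practice. Because no accepted gold standard exists, their
accuracy cannot be evaluated by cross-tabulation against a reference.
This package takes the latent class route: treat true malnutrition as an
unobserved binary state and estimate each instrument's sensitivity and
specificity jointly from the 2³ cross-classification of their binary
results.

## Rule engines

All thresholds are implemented literally as the instrument definitions
write them; boundary semantics are pinned by tests at BMI ∈ {18.49, 18.5,
19.99, 20.0, 21.99, 22.0}, weight loss ∈ {5.0, 5.01, 10.0, 10.01, 20.0},
FFMI ∈ {15, 17} and PG-SGA score ∈ {1, 2, 3, 4, 8, 9}.

* **PG-SGA**: score 0–1 well, 2–3 mild, 4–8 moderate, ≥9 severe;
  malnourished iff score ≥2. The internal seven-component worksheet is out
  of scope; the score enters as a single integer.
* **ESPEN** (gated on a positive NRS-2002 screen): C1 BMI < 18.5; C2
  weight-loss clause (>10% at any time OR >5% in the last 3 months) AND
  BMI < 20 (<70 y) / < 22 (≥70 y); C3 same clause AND FFMI < 15 (women) /
  < 17 (men). Any condition suffices; all that fire are recorded.
* **GLIM** (same gate): phenotypic P1 weight loss (>5% within 6 months or
  >10% beyond), P2 low BMI (<18.5 under 70 y, <20 at ≥70 y — Asian
  cutoffs), P3 reduced muscle mass (anthropometric flag OR FFMI below the
  sex cutoff — either suffices); etiologic E1 reduced intake, E2 disease
  burden (the malignancy itself, in a cancer cohort). Malnourished iff at
  least one of each. Severity: severe iff loss ≥10% within 6 months or
  ≥20% beyond; else moderate.

Design choices where the definitions are silent:

* Diagnostic weight-loss thresholds are strict (`>`); severity thresholds
  are inclusive (`≥`). At the 10%/6-month boundary the severe rule takes
  precedence, so the moderate bands read [5, 10) within and (10, 20)
  beyond 6 months — this makes the severity partition exhaustive.
* GLIM malnutrition established only via low BMI or muscle mass (no
  qualifying loss) is graded **moderate** and flagged `severity-default`:
  the framework grades primarily on phenotype but publishes only
  weight-loss thresholds.
* A missing optional field (FFMI, muscle flag) makes the clause that needs
  it evaluate **false** and records a `warn:` entry on the diagnosis — a
  data-completeness issue, not an error.
* The ESPEN 3-month and GLIM 6-month loss windows are kept as distinct
  record fields. They are separate interview quantities, and a recent
  rapid loss with earlier regain can make the 3-month figure exceed the
  6-month one; the record invariant only requires the any-time maximum to
  dominate both.
* Whether ESPEN is gated on the same risk screen as GLIM is implied but
  not explicit in the consensus texts; both are gated identically here.

## Latent class model and sampler

With K = 3 conditionally independent tests in a single population the
model is just-identified (7 parameters vs 7 free cells), so flat Beta(1,1)
priors are the default; informative Beta hyperparameters can be supplied
per parameter. K = 2 in a single population is **not** identifiable
without informative priors and the fitter warns accordingly.

The sampler is conjugate data-augmentation Gibbs, not generic MCMC: per
sweep, (i) latent diseased counts per pattern z_y ~ Binomial(n_y,
πa_y/(πa_y+(1−π)b_y)) with a_y, b_y the class-conditional pattern
probabilities; (ii) π ~ Beta(a+Σz, b+N−Σz); (iii, iv) each Se_k / Sp_k
from its Beta full conditional. One sweep is O(2^K); the study-sized fit
(3 × 20,000 iterations at n = 3,182) takes a few seconds. K > 12 is
refused (table blow-up). Initial values are drawn from the priors per
chain, giving overdispersed starts. All draws are deterministic given the
per-chain seeds.

**Label switching.** The two-class model is invariant under π → 1−π,
Se_k ↔ 1−Sp_k (every cell probability is unchanged — tested directly).
`enforce_orientation` therefore mirrors every draw with Σ_k(Se_k+Sp_k) ≤ K
onto the mode where the tests are better than chance. It operates per
draw rather than as a single global relabel: a per-draw rule subsumes the
global one and additionally repairs chains that switch labels mid-run,
which a global flip cannot. The fraction of flipped draws is reported.

**Summaries and diagnostics.** Equal-tailed 95% credible intervals from
the pooled 2.5/97.5 percentiles (HPD intervals are deliberately not used —
equal-tailed matches how such analyses report CrIs). Gelman–Rubin
R̂ = sqrt(((n−1)/n·W + B/n)/W) per parameter; identical chains give
exactly sqrt((n−1)/n), chains stuck at distinct constants give W = 0,
reported as R̂ = ∞ with a warning. The automated verdict uses R̂ < 1.1.
Effective sample size uses Geyer's initial-monotone truncation of the
pooled autocorrelation.

## Discordance attribution

Each patient malnourished by ESPEN but not GLIM receives exactly one
primary pathway label, priority-ordered to mirror how such discordance
tables present mutually exclusive subgroups:

1. `C2-BMI-band` — C2 fired with BMI ∈ [18.5, 20) and age < 70, the
   weight-loss clause being satisfied via the GLIM-comparable 3-month
   route, so the more inclusive BMI cutoff is the ESPEN-specific driver;
2. `C2-WL-anytime` — the clause held only through “>10% at any time” with
   no GLIM-qualifying loss, so the broader time frame is the driver;
3. `C3-FFMI` — only C3 fired;
4. `C1` — BMI < 18.5;
5. `multiple` — several pathways jointly required.

Note one structural fact the attribution respects: a patient with low
FFMI fires GLIM's P3 as well, so `C3-FFMI` cannot arise among ESPEN-only
patients generated under fully consistent data — it appears only when the
muscle-mass fields disagree, as they can in real registries. Group
comparisons use the Pearson chi-square test without continuity correction,
switching mechanically to Fisher's exact test (two-sided, by
hypergeometric enumeration) whenever any expected cell count is below 5.
Percentages are printed to one decimal with round-half-up, the convention
of clinical baseline tables. The chi-square/Fisher computations are thin
validated wrappers over `scipy.stats`; the test suite checks them against
the textbook Pearson formula and an independent enumeration oracle.

## Survival machinery

Implemented from first principles (the established `lifelines`
implementations serve as cross-check oracles in the test suite only):

* **Kaplan–Meier**: product-limit over distinct event times; censorings at
  an event time remain at risk for that event. Median = smallest t with
  S(t) ≤ 0.5, reported as absent (not an error) when S never crosses 0.5.
* **Log-rank**: (O−E)ᵀV⁻¹(O−E) with hypergeometric variance, one group
  dropped; df = G−1. The classical identity with the Cox score test at
  β = 0 (binary covariate, no ties) is asserted to 1e−8.
* **Cox**: damped Newton–Raphson (step-halving on the partial likelihood)
  with Efron tie handling by default — monthly follow-up times are heavily
  tied, where Efron is the better-behaved correction — and Breslow
  selectable for cross-checks. SEs from the inverse observed information;
  Wald 95% CIs exp(β ± 1.96·SE), matching how hazard ratios are reported
  in the target literature; no profile-likelihood intervals. Constant
  covariates get β = 0 with zero SE; non-convergence and suspected
  monotone likelihood (|β| > 10) are flagged on the returned fit, never
  silent. Proportionality diagnostics beyond this are out of scope.

`survival_by_nutrition` stratifies per tool, binary (well vs malnourished)
or severity-graded (PG-SGA: well / possibly-or-moderate (2–8) / severe
(≥9); GLIM: well / moderate / severe). ESPEN defines no severity grades,
so requesting a severity split for ESPEN is refused explicitly rather than
silently degraded to binary.

## Synthetic cohorts

Two generators share one `CohortSpec`, because two different downstream
needs pull in opposite directions:

* **Latent-class mode** draws test panels directly from the model —
  Bernoulli(π) status, then conditionally independent results with the
  specified Se/Sp. This satisfies the fit's assumption *exactly* and is
  what the recovery study uses. Defaults: n = 3,182, π = 0.25,
  Se = (0.80, 0.84, 0.57), Sp = (0.99, 0.43, 0.81) for (PG-SGA, ESPEN,
  GLIM) — the accuracies this analysis estimates, used as generating
  truth. The true prevalence is latent in any real cohort; 0.25 is a
  convention, not an observed value.
* **Mechanistic mode** draws covariates (age ~ N(67, 10²) giving ~58% aged
  ≥65; 59.7% male; class-dependent BMI and FFMI; weight-loss histories;
  PG-SGA scores; screen and intake flags) and lets the criteria module
  produce the diagnoses. Weight-loss history follows one of four temporal
  profiles — stable, progressive (6-month window), recent-rapid (3-month
  loss exceeding the net 6-month figure after partial regain), historic
  (>10% at some past time, quiet windows) — and current BMI/FFMI are
  depressed by the loss, which couples GLIM's phenotypic criteria to
  ESPEN's clauses. Phenotypically compromised patients without a
  window-qualifying loss usually receive a historic one, mirroring how a
  registry's any-time clause captures essentially every such patient.
  Under the defaults ESPEN diagnoses more patients than GLIM and the
  ESPEN-only group is dominated by the any-time weight-loss and BMI-band
  pathways.

  Because the tests share covariates, conditional independence holds only
  approximately in mechanistic cohorts: a latent class fit on them is
  *expected* to drift from the generator's nominal accuracies. This is a
  feature — it shows what the model's assumption costs — but it means all
  calibration claims about the fit rest on latent-class-mode cohorts.

**Survival**: event times Weibull (shape 1 = exponential default, shape
exposed for robustness checks) with hazard `hazard_scale · hr^severity`;
independent exponential censoring. Times are in months; defaults
hazard_scale = ln2/60 (baseline median 60 months), censoring ln2/50
(median follow-up of the order of 3 years), hr_moderate = 1.29,
hr_severe = 1.50 — effect sizes in the 1.2–1.7 range reported for
malnutrition in colorectal-cancer cohorts.

**Missingness** is MCAR only, over the categorical baseline fields (sex,
muscle flag, intake flag, screen flag); survival time, event status and
the PG-SGA score are never masked. Mode imputation fills each column with
its most frequent observed value (ties break to the smallest value);
`complete_case_subset` implements the complementary sensitivity analysis.
No informative-missingness mechanism is modelled.

What passing tests on these cohorts do **not** show: fidelity to any real
registry's joint covariate distribution (only selected marginals are
matched), multi-centre structure, informative censoring or missingness,
or conditional *dependence* between tests (a random-effects LCM is out of
scope).

## Operating characteristics (computed by `analysis/06` and the acceptance script)

* Latent class recovery at the study size (50 replicates, n = 3,182, flat
  priors, 3 × 20,000 iterations): every true parameter inside its 95% CrI
  in ≥90% of replicates; max |posterior-mean bias| < 0.03.
* Log-rank type-I error within (0.03, 0.07) at α = 0.05 over 1,000 null
  replicates (n = 200 per replicate).
* Cox recovery: mean estimated HR for severe malnutrition within
  (1.4, 1.6) of the true 1.50 over 20 seeds at n = 3,000.

## Numerical conventions

* Test order is fixed everywhere as (PG-SGA, ESPEN, GLIM); pattern index
  = Σ_k y_k·2^k.
* Cohort CSVs use the frozen column schema in `nutrilcm.cohort`, missing
  token `""`, and fixed float formatting, so one seed yields a
  byte-identical file.
* All randomness flows from explicit seeds (one per MCMC chain; generator
  seeds in `CohortSpec`); pipeline reports are byte-identical across
  repeated runs of the same configuration.
* CLI exit codes: 0 success, 2 schema/validation error, 3 latent class
  fit flagged not converged (outputs still written).
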