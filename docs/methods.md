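# Methods

## Cohort model

A cohort is a flat per-subject table. Moderate-to-severe COPD is defined
spirometrically: cases have post-bronchodilator FEV₁ < 80 % predicted and
FEV₁/FVC < 0.7; controls have FEV₁ ≥ 80 % predicted and FEV₁/FVC ≥ 0.7.
The two discordant quadrants are excluded from both groups: GOLD 1 (mild
obstruction with preserved FEV₁) and PRISm (preserved ratio with impaired
spirometry). Records with incomplete spirometry get a missing status and
drop out of COPD models only; every complete-spirometry record maps to
exactly one of case/control/excluded.

Family history is the parent-report composite of COPD, chronic bronchitis
and emphysema. The primary coding treats an "unknown" response as "no";
`exclude_unknown` instead drops subjects whose every contributing response
is unknown (a sensitivity coding), and `eclipse_harmonized` restricts the
composite to chronic bronchitis and emphysema for questionnaires without a
COPD item.

The PRS enters analyses as a per-cohort z-score. Standardization uses the
sample mean and SD (ddof = 1) over all scored subjects in the cohort —
before outcome filtering — so "per SD" refers to the cohort's scale rather
than an outcome-dependent one. The dichotomized form flags scores strictly
above the empirical 2/3 quantile (linear-interpolation quantile); ties at
the cut fall below, a deterministic convention. The top tertile is used so
that the flagged fraction (~1/3) matches the typical prevalence of a
positive family history, making the two exposures' odds ratios comparable.

Descriptive summaries report mean (SD) when both groups pass a
Shapiro–Wilk screen at α = 0.05 (on a fixed-seed subsample capped at 5000,
since the test degenerates at large n) and median (IQR) otherwise, with
Welch t / Wilcoxon rank-sum / chi-square comparison p-values attached for
reporting only. "Frequent exacerbations" means more than one exacerbation
in the prior 12 months; counts are validated as integers, so this
coincides with "two or more per year".

## Synthetic-cohort generator

The generator encodes the causal structure the analyses assume
(exposure → mediator → outcome with shared covariates):

- FH ~ Bernoulli(p), default p = 0.33;
- PRS_raw ~ Normal(a·FH, 1). The shift a is the exposure–mediator link.
  Default a = 0.153: by the closed form r_pb = a√(pq)/√(1+a²pq),
  r_b = r_pb·√(pq)/φ(Φ⁻¹(p)), this yields a biserial correlation of
  0.093 at p = 0.33 — the weak coupling regime of interest. (Note the
  biserial is ≈1.3× the point-biserial at this prevalence; the two are
  easy to conflate.)
- logit P(case) = β₀ + β_FH·FH + β_PRS·PRS + γ·FH·PRS + β_age·(age−μ_age)
  + β_sex·male + β_py·(py−μ_py), with defaults β_FH = ln 1.67,
  β_PRS = ln 2.11, γ = 0. Age and pack-years enter centered so β₀ alone
  sets the case fraction at covariate means (default β₀ = 0 → roughly
  half cases, the enriched case–control design the analyses target; a
  rare-outcome regime for mediation checks uses β₀ ≈ −3.5).
- Spirometry is back-filled from truncated normals on the correct side of
  the diagnostic thresholds given the drawn status (cases: FEV₁pp ~
  TN(49, 18) below 80 and ratio ~ TN(0.48, 0.13) below 0.7; controls
  mirrored above the thresholds, matching typical group means). The
  generator therefore produces no excluded subjects; exclusion logic is
  exercised by hand-built fixtures.
- Covariates: age ~ N(62, 8.5) clipped to the 45–90 enrolment window,
  pack-years ~ TN(45, 25) ≥ 10 (heavy-smoker inclusion criterion), 46%
  male, 38% current smokers; five ancestry PCs as independent standard
  normals (placeholders for adjustment, carrying no confounding signal).
- Secondary outcomes (SGRQ, 6-minute walk, BODE, death, exacerbations,
  quantitative CT traits) follow simple linear/logistic models in case
  status, FH and PRS with plausible scales, so every pipeline stage has
  data; their coefficients are conveniences, not calibrated targets.
- Optional case:control resampling to fixed target counts reproduces a
  heavily imbalanced replication cohort (e.g. 1713:147).

Randomness uses one master `SeedSequence` spawned into independent child
streams per block (covariates, exposure, mediator, outcome, spirometry,
secondary, sampling, PCs), so the same seed gives a bit-identical table
and enabling one block never perturbs another.

What the generator does **not** emulate: linkage structure or genotypes
(the PRS is a single abstract score), ancestry-specific PRS attenuation,
questionnaire recall error, shared-environment confounding between FH and
COPD, longitudinal follow-up, and real missingness patterns. Passing
tests therefore demonstrate correctness of the estimators under the
assumed data-generating structure, not robustness to those violations.

## Regression engines

Logistic models are fitted by Newton/IRLS with a fixed start at β = 0,
step-halving so the (penalized) log-likelihood never decreases, and
convergence when the max-abs score < 1e-8 (cap 50 iterations) — fully
deterministic. Apparent separation is detected two ways (divergence after
the iteration cap, or convergence of the score with all residuals below
1e-4, which means the likelihood sup is on the boundary) and raises an
error advising the Firth estimator.

The Firth variant maximizes ℓ(β) + ½ log det I(β) via the hat-adjusted
score Σᵢ (yᵢ − pᵢ + hᵢ(½ − pᵢ)) xᵢ; estimates stay finite under
separation, and in a saturated 2×2 the estimator equals the Haldane +0.5
cell correction (used as a test oracle). Wald CIs are reported on the
penalized estimates; profile-penalized-likelihood intervals are out of
scope. Firth is the default recommendation for heavily imbalanced
cohorts.

Design conventions: sex is coded male = 1 (female reference), categorical
covariates expand to treatment dummies, genetic PCs (default 5,
configurable) enter only alongside the PRS (models 2 and 3), and
missingness is handled complete-case per model. Outcome-specific
covariates follow the analysis plan: exacerbation outcomes add baseline
FEV₁ %predicted and current smoking; 6-minute walk adds height and
weight; death adds BODE; CT traits add scanner. Continuous outcomes use
OLS (via statsmodels) with classical SEs; MSE is RSS/n (denominator n, a
documented convention), adjusted R² the usual (1−R²)(n−1)/(n−p−1)
complement. Death is modelled with logistic regression on baseline
status; no survival modelling is attempted.

## Discrimination, calibration

AUROC is the Mann–Whitney concordance (ties ½), computed by midranks; the
variance and the paired two-model comparison use DeLong structural
components. Comparisons are two-sided; a zero-variance contrast (e.g.
self-comparison) is flagged degenerate with p = 1 at delta = 0. Metrics
are apparent (in-sample), matching common practice for these cohort
analyses; cross-validation is deliberately not the default. Known caveat:
the DeLong test applied in-sample to *nested* models is anticonservative;
the test statistic itself is calibrated (checked under a clean null), and
the nested-model usage mirrors field practice rather than endorsing it.
The scaled Brier score is 1 − Brier/(p̄(1−p̄)), i.e. improvement over the
constant-prevalence forecaster: 1 = perfect, 0 = no better than
prevalence, negative = worse.

## Attributable fractions and interaction

AF_exposed = (OR−1)/OR, valid as a risk-fraction approximation in the
case–control setting; AF_population multiplies by the exposure prevalence
among cases (Miettinen's case-based form). The method label and inputs
travel with the result so an alternative (e.g. Levin) can be swapped in;
population AFs depend on this choice and on prevalence estimates, so only
AF_exposed is treated as externally checkable.

Additive interaction: RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 from a single
covariate-adjusted logistic fit of the four-level FH × top-tertile
exposure; the CI is delta-method (Hosmer–Lemeshow) from the coefficient
covariance, and the identical quantity computed from the product-term
parameterization agrees to machine precision (same model space). The
test's sidedness is configurable (two-sided default; published RERI
p-values whose CI covers zero suggest some analyses report one-sided).
A RERI computed from a continuous PRS evaluates the contrast at +1 SD.
Multiplicative interaction is the Wald test on the FH × PRS product term,
with an LRT cross-check. Note that γ = 0 with nonzero main effects is
*not* an additive null — two purely multiplicative risk factors always
yield RERI = (OR₁₀−1)(OR₀₁−1) > 0 — so RERI type-I error is calibrated
under the complete null, which is null on both scales.

## Correlation and mediation

The biserial correlation has two estimators: the closed-form conversion
r_b = r_pb·√(p(1−p))/φ(Φ⁻¹(p)) of the Pearson point-biserial, and a
two-step latent-bivariate-normal ML fit on the 2×10 table formed by
cutting the score into 10 equal-count bins (thresholds fixed at the
empirical margins' normal quantiles, ρ maximizing the multinomial
likelihood). The two agree on latent-normal data; the p-value reported is
the point-biserial t-test in both cases. The "10 bins" procedure is
ambiguous in the field; both implementations are provided and compared in
tests.

Mediation uses the imputation-based natural-effects estimator: fit
logit P(Y | x, m, c) (exposure–mediator interaction off by default,
configurable); expand each record over hypothetical exposure x₀ ∈ {0,1}
keeping the observed mediator and the exposure x₁ that generated it;
impute E[Y(x₀, M(x₁))] from the outcome model; fit the natural-effects
model logit E[Y] ~ x₀ + x₁ + c on the expanded data by binomial
quasi-likelihood. Coefficient on x₀ = NDE, on x₁ = NIE (log-odds scale);
total = NDE + NIE by construction; proportion mediated = NIE/total.
Under a rare outcome the NIE approximates the mediator-model shift times
the outcome-model mediator coefficient (a·β_PRS), the product-of-
coefficients oracle used in tests. Inference is a seeded nonparametric
bootstrap over subjects (default B = 1000, percentile CIs); the
proportion-mediated CI is withheld unless the bootstrapped total effect
keeps one sign in ≥ 97.5 % of replicates. The estimator assumes no
unmeasured exposure–outcome, mediator–outcome or exposure–mediator
confounding beyond the adjusted covariates; this is stated, not testable.

## Meta-analysis

Fixed-effect inverse-variance pooling on the log scale; Q, df, and
I² = max(0, (Q−df)/Q)·100. SEs recovered from printed 95 % CIs use
(ln U − ln L)/3.92 and inherit the printing precision, so heterogeneity
checks against published tables are approximate at the rounding level.
A DerSimonian–Laird random-effects variant exists behind a flag for
completeness; the pipeline reports fixed effects. Three-cohort pooling
(two discovery ancestry strata plus the replication cohort) is the
default. Bonferroni thresholds are echoed as table annotations, never as
filters.

## Problem sizes and numerical conventions

Stochastic checks use sizes chosen so the relevant asymptotics hold while
the whole suite stays desk-scale: OR recovery at n = 50,000 over 20
seeds; mediation recovery at n = 100,000 in the rare-outcome regime
(point estimates; the product-of-coefficients oracle concerns the
estimate, not its CI); interaction-test calibration over 1,000 replicates
at n = 1,000 (cell counts ~60+ in the smallest joint-exposure cell, the
Wald regime); delta-vs-bootstrap RERI comparison at n = 20,000. Bootstrap
B values in tests are reduced (50–200) where only determinism or bracket
behaviour is asserted.

Degenerate inputs fail loudly: zero-variance PRS, single-class outcomes,
rank-deficient designs (collinear columns named via pivoted QR), empty
joint-exposure cells, non-overlapping exposure groups, unreachable
case:control targets. Cohort CSVs round-trip bit-exactly (floats are
re-parsed through the correctly rounded parser; pandas' fast parser can
be one ulp off).

## Known limitations

- In-sample performance metrics and nested-model DeLong comparisons
  (documented anticonservativeness).
- AF_population depends on the chosen formula and printed prevalences;
  treated as descriptive.
- The natural-effects bootstrap refits two logistic models per replicate;
  B = 1000 on very large cohorts is compute-heavy (scale B or n).
- The generator's secondary-outcome models are structural conveniences;
  only the exposure/mediator/outcome block is calibrated to published
  effect sizes.
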