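# famprs

Family history versus a polygenic risk score (PRS) as predictors of COPD:
a tested, reusable analysis pipeline for smoker case–control cohorts.

A parental history of COPD, chronic bronchitis or emphysema and a
genome-wide polygenic score both predict moderate-to-severe COPD, but they
may carry redundant or complementary information. `famprs` implements the
full comparison for epidemiologists working with COPDGene/ECLIPSE-like
cohort tables (or the bundled synthetic-cohort generator):

- **Cohort derivation** — spirometric case/control assignment
  (case: FEV₁ %predicted < 80 and FEV₁/FVC < 0.7; control: both preserved;
  GOLD 1 and PRISm excluded), family-history harmonization
  ("unknown" → "no", with exclude-unknown and chronic-bronchitis/emphysema-only
  sensitivity codings), per-cohort PRS standardization and top-tertile
  dichotomization, Table-1-style summaries.
- **Nested risk models** — for each outcome, model 1
  `outcome ~ FH + C`, model 2 `outcome ~ PRS + C + PCs`, model 3
  `outcome ~ FH + PRS + C + PCs`, where C is age, sex and pack-years plus
  outcome-specific covariates; logistic maximum likelihood, Firth-penalized
  logistic for imbalanced samples, and OLS for continuous outcomes.
- **Predictive performance** — AUROC with DeLong variance and the paired
  DeLong test for correlated ROC curves, scaled Brier scores, adjusted R²
  and MSE.
- **Attributable fractions and interaction** — AF_exposed = (OR−1)/OR,
  Miettinen case-based AF_population, joint-effect odds ratios of FH × top
  PRS tertile, multiplicative (product-term) interaction, and additive
  interaction via RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 with a delta-method CI.
- **Mediation and correlation** — biserial FH–PRS correlation (closed-form
  and decile-binned latent-normal ML), and an imputation-based
  natural-effects model decomposing the FH effect into natural direct and
  indirect (through PRS) log-odds effects, with bootstrap CIs.
- **Meta-analysis** — inverse-variance fixed-effect pooling of per-cohort
  model-3 estimates with Cochran's Q and I².

## Worked example

```python
from famprs import (SimulationConfig, generate_synthetic_cohort, derive_cohort,
                    auc_with_ci, joint_effects, natural_effects_mediation)
from famprs.regression import fit_three_models, build_design

cfg = SimulationConfig(n=20_000, seed=42)       # study-condition defaults
df = derive_cohort(generate_synthetic_cohort(cfg))
fits = fit_three_models(df, "copd_case")
print(fits[3].to_frame())                        # model-3 odds ratios
```

With the default generator (FH prevalence 0.33, OR 1.67 per positive
family history, OR 2.11 per SD of PRS, mediator shift 0.153) this prints:

```
model 3 coefficients:
                   or  or_ci_low  or_ci_high
family_history  1.784      1.669       1.907
prs_z           2.117      2.045       2.191
model 1 AUC 0.674 (95% CI 0.666-0.681)
model 2 AUC 0.740 (95% CI 0.733-0.747)
model 3 AUC 0.749 (95% CI 0.742-0.756)
model 3 vs 2: delta AUC 0.0089, DeLong p 6.6e-17
RERI 1.87 (95% CI 1.24 to 2.51)
biserial FH-PRS correlation 0.083 (p=1.7e-19)
NDE 0.518, NIE 0.090, proportion mediated 14.9% (95% CI 11.6% to 17.9%)
```

Both predictors retain their effects when modelled together (complementary
information); the model with both discriminates slightly but significantly
better than PRS alone; the RERI is positive because two multiplicative
risk factors always produce excess risk on the additive scale; and about
15% of the family-history effect travels through the PRS — mirroring the
structure the generator encodes. The pipeline version of the same run is

```bash
famprs report --config examples/pipeline.yaml --seed 42 --out-dir out/
```

which writes tidy CSVs (`models.csv`, `performance.csv`,
`attributable_fractions.csv`, `interaction.csv`, `mediation.csv`,
`meta.csv`, `table1.csv`), a run manifest and a JSON-lines log.

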