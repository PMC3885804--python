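# pprpanel

Measurement and dynamic modelling of adherence to inhaled corticosteroids
(ICS) from primary-care prescribing records.

Adherence to preventer inhalers is the main modifiable cause of treatment
failure in asthma, and prescribing databases (CPRD-style primary-care
extracts linked to hospital episodes) are the only place it can be observed
at population scale in the UK. `pprpanel` is for pharmacoepidemiologists
and health-services researchers who want to

1. turn raw prescribing records into an annual **prescription possession
   ratio (PPR)** — the percentage of days in each calendar year covered by
   prescribed ICS supply — under five explicit strategies for handling
   overlapping supply, year-boundary spill-over, denominator adjustment and
   censoring at 100 %;
2. phenotype each patient-year clinically: asthma exacerbations split into
   hospital-recorded (primary ICD-10 J45.x/J46) and primary-care managed
   (oral prednisolone "bursts": < 10 days per prescription, < 90
   prednisolone days per year, ≤ 20 tablets at 25 mg or ≤ 112 at 5 mg),
   BTS/SIGN treatment step (maintenance oral steroids ⇒ step 5), and poor
   control (> 10 SABA doses/day on average);
3. model adherence dynamics on the resulting unbalanced panel with a
   from-scratch **system GMM (Blundell–Bond)** estimator:

   PPR_it = α₁ PPR_{i,t−1} + α₂ PPR_{i,t−2} + γ Y_it + β₀ + β′X_it + λ_i + U_it

   where λ_i is a patient fixed effect, the exacerbation count Y_it is
   endogenous, prior-year exacerbation indicators are predetermined, and
   age, years in study, SABA use, step dummies and step change are
   exogenous. The estimator supports collapsed instruments, one- and
   two-step weighting, Windmeijer-corrected standard errors, the Hansen J
   overidentification test and Arellano–Bond AR(1)/AR(2) diagnostics.

Because the real cohort data are not publicly available, the package ships
a seeded synthetic cohort generator with known ground truth, in two modes:
a direct patient-year panel for estimator validation, and raw four-table
records (patients, therapy, clinical events, hospital episodes) that
exercise the entire pipeline. See `docs/methods.md` for the model, the
measurement rules and the generator design.

## Worked example

Simulate a 2,000-patient panel from known coefficients and re-estimate
them:

```python
import pprpanel as pp

truth = pp.TruthParameters(n_patients=2000, seed=1)
panel, latent = pp.simulate_panel(truth)
res = pp.fit_system_gmm(panel)
print(res.summary().round(3))
```

```
                   estimate     se  t_stat
const                21.703  2.456   8.836
age_years             0.120  0.031   3.920
years_in_study        0.315  0.122   2.587
saba_high             4.973  0.917   5.423
step3                -2.131  0.737  -2.893
step4                -2.215  0.966  -2.293
step5                -0.926  1.511  -0.613
step_change           2.342  0.611   3.834
ppr_lag1              0.536  0.022  24.532
ppr_lag2              0.094  0.019   5.060
exac_total            1.630  2.199   0.741
prior_hosp            1.429  3.640   0.393
prior_primary        -0.355  0.787  -0.451
prior_interaction    -0.490  5.584  -0.088
```

With `truth.coefficients()` as the data-generating values (α₁ = 0.503,
α₂ = 0.102, β_age = 0.110, …), the two-step collapsed system-GMM estimates
land on truth within sampling error: adherence is strongly persistent
(ppr_lag1 ≈ 0.54), improves with age and a worsening treatment step, and
the diagnostics behave as theory predicts —

```
Hansen J 27.03 (df 25, p 0.355)       # instruments not rejected
AR(1) z -22.57 (p 0.0000)             # expected: differencing induces MA(1)
AR(2) z 0.01  (p 0.991)               # no deeper serial correlation
```

The same model can be run from the shell over the full record pipeline
(simulate → impute → PPR → classify → panel → fit):

```bash
pprpanel run-all --seed 42 --out run/ --strata gender
```

which writes the four raw tables, `therapy_imputed.csv`,
`patient_year_ppr.csv` (all five strategies, long format),
`patient_year_clinical.csv`, `panel.csv`, `estimates.csv`,
`diagnostics.json` and a `manifest.json` recording the seed and per-stage
row counts; identical seed and config reproduce every file byte for byte.

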