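# Methods

`pprpanel` measures adherence to inhaled corticosteroids (ICS) from
primary-care prescribing records and models its dynamics on an unbalanced
patient-year panel. This note records the model, the measurement rules, the
synthetic-data design and the numerical choices, in enough detail to
reproduce or modify any of them.

## The adherence measure

For each patient, follow-up `[index_date, exit_date)` is divided into
consecutive calendar-year intervals (half-open; the first and last are
truncated at entry and exit). Each prescription contributes a supply window
`[issue_date, issue_date + duration_days)`. The prescription possession
ratio for a patient-year is

    PPR = 100 * (days of medicine prescribed in the interval)
              / (days in the interval)

Five strategies resolve the ambiguities that overlapping and
boundary-spanning prescriptions create:

| strategy | numerator | excess days | denominator | cap |
|---|---|---|---|---|
| 1 | overlap included (day multiplicity summed) | pass to next interval | 365 | – |
| 2 | overlap excluded (union of covered days) | pass to next interval | 365 | – |
| 3 | overlap included | shared across spanned intervals ∝ denominators | 365 | – |
| 4 | overlap included | pass to next interval | interval length − gap days | – |
| 5 | as strategy 1 | | | censored at 100 |

Notes and edge cases:

* **365-day denominator.** Complete years use 365 even in leap years;
  truncated first/last intervals use true day counts.
* **Union cap.** Under strategy 2 a fully covered leap year would count 366
  days against a 365-day denominator; the union numerator is capped at the
  denominator, so strategies 2 and 5 are bounded at 100 % by construction.
* **Excess days.** Days of supply falling after the last interval are
  discarded and reported (`terminal_excess`); days before entry likewise
  (`pre_followup`). This gives exact conservation under strategy 1:
  numerators + discarded days = total prescribed days, which the tests
  assert to the day.
* **Proportional sharing (strategy 3).** A window's in-follow-up days are
  allocated across every interval it touches in proportion to those
  intervals' denominators. This is one reasonable reading of "share excess
  proportionally"; it is descriptive output only — the modelled measure
  (strategy 5) never depends on it.
* **Adjusted denominator (strategy 4).** Gaps attributable to
  prescriptions whose duration could not be resolved are subtracted from
  the interval length: each unresolvable prescription opens a gap of the
  per-form median duration starting at its issue date; gap days are
  counted as a union. A patient-year whose adjusted denominator reaches 0
  is dropped with a log entry.
* Strategy 5 (censored base case) is the modelled measure, following the
  clinical argument that patients do not discard leftover doses and gain
  nothing beyond full coverage.

## Duration imputation

Durations missing from the therapy file are resolved by a fixed cascade:
recorded duration → total doses (packs × doses/pack) ÷ daily dose → the
patient's most recent earlier daily dose for the same drug class → the
cohort median daily dose by dosage form → unresolvable. Conventions that
the source rules leave open and that we fixed for reproducibility:

* computed durations are rounded to the nearest integer day, ties upward,
  with a floor of 1 day;
* a recorded daily dose of 0 is treated as missing (the cascade continues);
* the prior-prescription lookback is unbounded within the patient record;
* pack-size outliers can be snapped to a configurable per-form list of
  valid sizes (a stand-in for formulary pack data, which is not shipped);
  snapping is off unless a list is supplied.

Every record carries a provenance flag; imputation never alters a recorded
duration.

## Clinical phenotyping

* **Primary-care exacerbation**: an oral prednisolone prescription with
  duration < 10 days, total prednisolone days in the year < 90, and
  (qty ≤ 20 at 25 mg) or (qty ≤ 112 at 5 mg). Quantity is the tablet count
  (`qty × doses_per_pack`, with `doses_per_pack` defaulting to 1 for oral
  forms). A prednisolone record failing these criteria marks the
  patient-year as BTS/SIGN step 5 (maintenance oral steroids).
* **Hospital exacerbation**: an inpatient episode whose primary ICD-10
  code is in the asthma block — J45 with any subcode, plus J46
  (configurable). A literal "codes ordered below J45" reading would sweep
  in unrelated respiratory disease and is rejected.
* **Keyword events**: coded clinical events are matched case-insensitively
  against configured keyword groups ("asthma"+"exacerbation" → primary
  care, "emergency prednisolone" → primary, "admit to hospital" →
  secondary), standing in for Read-code lists that are not public.
* **De-duplication**: exacerbation signals within 14 days of one another
  (configurable) count as a single clinical episode. Secondary-care keyword
  events within the window of a hospital admission are absorbed by it;
  unlinked ones count toward the exacerbation total but not the hospital
  indicator.
* **Treatment step below 5** is reconstructed from prescribing, since only
  the step-5 rule is given by the source criteria: high-dose ICS
  (> 800 µg/day, computed as daily dose × strength) plus an add-on
  controller (LABA/LTRA) → step 4; ICS + add-on → step 3; ICS alone →
  step 2. The `strength` column carries mg for oral steroids and µg per
  actuation for inhaled products.
* **Poor control**: average SABA use strictly over 10 doses/day across the
  year.

## The dynamic panel model

The modelled relationship is

    PPR_it = α₁ PPR_{i,t−1} + α₂ PPR_{i,t−2} + γ Y_it + β₀ + β′X_it + λ_i + U_it

with patient fixed effect λ_i, current-year exacerbation count Y_it
(endogenous: adverse events and adherence shocks share causes),
predetermined prior-year care-setting indicators, and strictly exogenous
controls (age, years in study, SABA flag, step dummies with step 2 as
baseline, annual step change). Estimation panels require two consecutive
lags, so only patients with three or more consecutive recorded years
contribute; a gap year breaks the lag chain because α is a one-year
dynamic coefficient.

### System GMM

The estimator stacks the first-differenced equation (fixed effect removed)
with the level equation:

* difference equation — instruments are lagged levels: dependent and
  endogenous variables from lag 2 to lag `1 + depth` (depth 4 by default),
  predetermined from lag 1 to `depth`; exogenous regressors instrument
  themselves by their own differences;
* level equation — lag-1 differences of dependent/endogenous/predetermined
  variables (valid under mean stationarity), levels of exogenous
  regressors, and the intercept (which enters the level equation only).

Defaults follow common practice for this estimator family: collapsed
instrument columns (one per variable × lag distance) to curb instrument
proliferation at T up to 14; two-step estimation with the clustered
optimal weight; Windmeijer's finite-sample correction of two-step standard
errors. All are configurable (`GMMSpec`). One-step weighting uses the
first-difference covariance pattern (2 on the diagonal, −1 for adjacent
periods) on the difference block and the identity on the level block.

Numerical choices:

* missing instrument cells are zero-filled and unbalancedness handled by
  per-patient period masks;
* all-zero and exactly duplicated instrument columns are dropped
  deterministically (age and years-in-study difference to the same
  constant, for example);
* `G′WG` is solved by least squares with a pseudo-inverse for the
  variance, because rare-event dummies (prior-year hospital admission and
  the interaction) make the normal equations near-singular in small
  samples;
* singular weighting matrices receive an escalating ridge with a flag in
  the result; a non-positive Windmeijer-corrected variance falls back to
  the uncorrected two-step variance, flagged;
* Hansen's J is the minimized two-step criterion with the optimal weight
  at the final estimates, df = instruments − parameters; the
  Arellano–Bond AR(s) statistic uses the standard three-term variance with
  the estimation correction;
* degenerate case: no dynamics and no endogenous/predetermined regressors
  reduce the estimator to the exactly identified level equation, i.e.
  pooled OLS (verified against `statsmodels` in the tests).

## Synthetic cohorts

The generator is the package's test bed: it simulates the latent model
with known coefficients (defaults are the all-patients fitted estimates)
and, in record mode, re-expresses each patient-year as raw prescribing and
event rows.

Nuisance processes, chosen once for plausibility against the cohort
descriptives (mean step ≈ 2.7, SABA flag ≈ 4 %, ≈ 0.3 exacerbations/year):

* follow-up length uniform on {3,…,10} years; entry age uniform 12–60;
* treatment step follows a Markov chain on {2,3,4,5} with persistence
  0.85 and ±1 moves; SABA poor-control flag Bernoulli with
  step-increasing probability (2–20 %);
* fixed effects λ ~ N(0, 15²); model error U ~ N(0, 18²); PPR measurement
  noise defaults to 0 in direct mode (the model error already enters the
  latent value, and the source model never separates the two variances).

The exacerbation process is a Poisson count whose log-rate contains four
terms: a mild protective effect of last year's latent adherence
(−0.004 per point — better-covered patients exacerbate less), a
patient-level proneness (frailty, sd 0.8 on the log scale — "frequent
exacerbators"), an AR(1) proneness process (persistence 0.8, stationary
sd 0.7 — prolonged bad spells such as viral seasons), and a shock shared
with U_it (loading 0.5, correlation 0.3 with U) that makes the count
endogenous. Counts split 5 %/95 % into hospital and primary-care events.
The frailty and AR(1) terms are excluded from the adherence equation; they
exist so that lagged counts are *relevant* instruments — without them the
count is almost pure Poisson noise, the endogenous coefficient is weakly
identified, and two-step GMM's weak-instrument bias leaks into the
autoregressive coefficients. A validation design in which the estimator's
own identification conditions fail would test nothing.

Initial conditions: each patient's two pre-sample lags start at the
stationary mean implied by the entry covariates and the coupled
adherence/exacerbation recursion is burned in for 40 periods with those
covariates held fixed. This makes the simulated data mean-stationary, the
assumption underlying the level-equation moments.

Record mode emits, per patient-year: ICS prescriptions tiling
`round(3.65 × clip(A, 0, 100))` supply days in 28-day units (final
partial pack exact unless cross-year overshoot is drawn), with
configurable probabilities of early refill (overlap), year-end overshoot
and blanked durations (quantity and dose fields kept, so imputation can
recover the duration exactly); SABA packs totalling > 3,650 doses when the
poor-control flag is set; a 5-day, 40-tablet, 5 mg prednisolone burst per
primary-care exacerbation, spaced > 14 days apart; monthly 30-day,
120-tablet maintenance prednisolone in step-5 years (failing every burst
criterion); J45.x/J46 admissions for hospital events; and keyword noise
events. In step-5 years primary-care exacerbations are emitted as coded
keyword events rather than bursts, because a burst in a year with ≥ 90
maintenance prednisolone days would fail the annual-days criterion by
construction. Follow-up is aligned to whole calendar years in record mode
so the supply target formula applies to every interval; truncated
intervals are exercised directly in the unit tests.

What record mode does **not** emulate: real product dictionaries and pack
heterogeneity, seasonality of prescribing, practice-level clustering,
transcription errors beyond blanked durations, and informative exit.
Passing tests therefore demonstrate that the pipeline inverts its own
generator and that the estimator recovers known truth under the stated
conditions — not that these rules are correct for any particular real
extract.

## Problem sizes used in validation

The test-suite's simulation scales are: 20 replicates of N = 2,000
patients for coefficient recovery (each Monte-Carlo mean within 3 MC
standard errors of truth), 200 replicates of N = 500 for diagnostic
calibration (Hansen J rejection close to the 5 % nominal level, AR(2)
near nominal, AR(1) rejecting), 1,000 fuzzed patients for the day-level
numerator oracle, and a 1,000-patient dense cohort for the censoring
bound. These sizes give stable Monte-Carlo verdicts at desk scale.

## Known limitations

* The pack-size snapping list stands in for formulary reference data; no
  duplicate/swap heuristics beyond it are implemented.
* Keyword matching is substring-based on term text, not a terminology
  mapping.
* Strategy 3's proportional rule is a reconstruction; alternatives exist.
* The estimator offers no orthogonal-deviations transform and no
  continuously-updated GMM; difference-only (Arellano–Bond) estimation is
  available only implicitly as a comparator in tests.
* Step assignment below step 5 is a guideline-based reconstruction from
  prescribing signals and would need review against local dosing
  conventions before use on real data.
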