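"""Seeded synthetic cohorts with known ground truth.

Two modes share one latent model of adherence:

* **direct panel mode** (:func:`simulate_panel`) simulates the patient-year
  panel straight from the dynamic fixed-effects equation

  .. code-block:: text

      A_it = b0 + a1 A_{i,t-1} + a2 A_{i,t-2} + g Y_it + b'X_it + lam_i + U_it
      PPR_it = A_it + measurement noise   (no 100 % cap)

  with patient fixed effects ``lam_i ~ N(0, sigma_lambda)``, idiosyncratic
  errors ``U_it ~ N(0, sigma_u)`` and an exacerbation count ``Y_it`` that is
  endogenous by construction: a standard-normal shock is shared between the
  Poisson log-rate of ``Y_it`` and ``U_it``. The Poisson log-rate decreases
  in lagged latent adherence (better-covered patients exacerbate less).
  Default coefficients are the fitted all-patients estimates that the
  package's estimator is expected to recover in simulation.

* **record mode** (:func:`simulate_records`) inverts the measurement
  pipeline: each patient-year's latent adherence is re-expressed as raw
  prescribing, clinical-event and hospital-episode rows (ICS supply windows
  that may overlap, span year ends or lack durations; SABA quantities
  consistent with the poor-control flag; prednisolone bursts satisfying the
  exacerbation criteria; maintenance prednisolone violating them for step-5
  years; ICD-10 J45/J46 admissions), so the whole
  read -> impute -> PPR -> classify -> panel -> fit chain can be checked
  against ground truth.

Everything is driven by one ``numpy`` Generator seeded from
``TruthParameters.seed``: identical seeds give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from typing import NamedTuple

import numpy as np
import pandas as pd

#: panel column order used in outputs and model reporting
TABLE_ORDER = ("const", "age_years", "years_in_study", "saba_high",
               "step3", "step4", "step5", "step_change",
               "ppr_lag1", "ppr_lag2", "exac_total",
               "prior_hosp", "prior_primary", "prior_interaction")


@dataclass
class TruthParameters:
    """Data-generating coefficients and nuisance-process settings.

    Coefficient defaults are the all-patients fitted values used as
    simulation truth throughout the test-suite; nuisance defaults are
    chosen for plausibility against the cohort descriptives (mean step
    near 2.7, SABA flag near 4 %, around 0.3 exacerbations per year).
    """

    beta0: float = 24.757
    beta_age: float = 0.110
    beta_years: float = 0.257
    beta_saba: float = 5.108
    beta_step3: float = -1.472
    beta_step4: float = -2.513
    beta_step5: float = -4.014
    beta_step_change: float = 2.595
    alpha1: float = 0.503
    alpha2: float = 0.102
    gamma_exac: float = 0.241
    beta_prior_hosp: float = 1.653
    beta_prior_primary: float = 0.942
    beta_prior_interaction: float = -0.378

    sigma_lambda: float = 15.0
    sigma_u: float = 18.0
    sigma_measure: float = 0.0

    n_patients: int = 2000
    t_min: int = 3
    t_max: int = 10

    step_persistence: float = 0.85
    step_start_probs: tuple = (0.55, 0.28, 0.12, 0.05)   # steps 2..5
    saba_prob_by_step: dict = field(default_factory=lambda: {2: 0.02, 3: 0.05,
                                                             4: 0.10, 5: 0.20})
    exac_base_rate: float = 0.28
    exac_adherence_slope: float = -0.004   # per latent-adherence point
    exac_shock_scale: float = 0.5          # loading of the shared shock
    exac_frailty_sd: float = 0.8           # patient exacerbation-proneness (log scale)
    exac_state_dep: float = 0.0            # log-rate bump after a year with an attack
    exac_ar_rho: float = 0.8               # persistence of exacerbation-prone periods
    exac_ar_sd: float = 0.7                # stationary sd of that process (log scale)
    exac_max: int = 15
    hospital_share: float = 0.05
    endo_rho: float = 0.3                  # corr(shared shock, U)
    burn_in: int = 40                      # pre-sample periods per patient

    seed: int = 0

    def validate(self) -> None:
        if abs(self.alpha1) + abs(self.alpha2) >= 1:
            raise ValueError("nonstationary persistence: |a1|+|a2| must be < 1")
        if self.sigma_lambda < 0 or self.sigma_u < 0 or self.sigma_measure < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if not (1 <= self.t_min <= self.t_max):
            raise ValueError("bad follow-up length range")

    def coefficients(self) -> pd.Series:
        """True coefficient vector in reporting order."""
        return pd.Series({
            "const": self.beta0, "age_years": self.beta_age,
            "years_in_study": self.beta_years, "saba_high": self.beta_saba,
            "step3": self.beta_step3, "step4": self.beta_step4,
            "step5": self.beta_step5, "step_change": self.beta_step_change,
            "ppr_lag1": self.alpha1, "ppr_lag2": self.alpha2,
            "exac_total": self.gamma_exac, "prior_hosp": self.beta_prior_hosp,
            "prior_primary": self.beta_prior_primary,
            "prior_interaction": self.beta_prior_interaction,
        })[list(TABLE_ORDER)]


@dataclass
class RecordOptions:
    """Raw-record emission knobs for record mode."""

    p_early_refill: float = 0.2      # next ICS issued before supply runs out
    p_cross_year: float = 0.2        # last ICS of the year may overshoot
    p_missing_duration: float = 0.1  # duration blanked (qty/dose kept)
    p_keyword_echo: float = 0.3      # coded event accompanying a burst
    p_noise_event: float = 0.2       # non-matching coded event per year
    start_year_min: int = 1997
    start_year_max: int = 2010


class RecordCohort(NamedTuple):
    patients: pd.DataFrame
    therapy: pd.DataFrame
    clinical: pd.DataFrame
    episodes: pd.DataFrame
    truth: pd.DataFrame


def _stationary_sd(p: TruthParameters) -> float:
    a1, a2, s = p.alpha1, p.alpha2, p.sigma_u
    denom = (1 + a2) * ((1 - a2) ** 2 - a1 ** 2)
    if denom <= 0:
        return s
    return s * np.sqrt((1 - a2) / denom)


def _step_chain(rng, n, p: TruthParameters) -> np.ndarray:
    steps = np.empty(n, dtype=int)
    steps[0] = rng.choice([2, 3, 4, 5], p=np.asarray(p.step_start_probs))
    stay = p.step_persistence
    for k in range(1, n):
        s = steps[k - 1]
        u = rng.random()
        if u < stay:
            steps[k] = s
        else:
            moves = [m for m in (s - 1, s + 1) if 2 <= m <= 5]
            steps[k] = moves[0] if len(moves) == 1 else moves[int(rng.random() < 0.5)]
    return steps


def simulate_panel(truth: TruthParameters) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the patient-year panel directly from the latent model.

    Returns ``(panel, cohort_truth)``. The panel holds the observed
    variables (uncensored ``ppr`` and regressors); the truth frame holds
    per patient-year latent adherence and per-patient fixed effects.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    stat_sd = _stationary_sd(truth)
    rho = truth.endo_rho
    rows, trows = [], []
    for i in range(truth.n_patients):
        pid = f"P{i + 1:06d}"
        T = int(rng.integers(truth.t_min, truth.t_max + 1))
        age0 = int(rng.integers(12, 61))
        gender = "male" if rng.random() < 0.5 else "female"
        lam = rng.normal(0.0, truth.sigma_lambda)
        frailty = rng.normal(0.0, truth.exac_frailty_sd)
        steps = _step_chain(rng, T, truth)

        # initial conditions from the stationary distribution of the coupled
        # adherence/exacerbation process: start both lags at the stationary
        # mean implied by the entry covariates, then burn the full recursion
        # (exacerbation feedback included) in with those covariates held
        # fixed, so the level-equation moment conditions (mean stationarity)
        # hold in the simulated data
        x0 = (truth.beta0 + truth.beta_age * age0 + truth.beta_years * 1
              + truth.beta_step3 * (steps[0] == 3)
              + truth.beta_step4 * (steps[0] == 4)
              + truth.beta_step5 * (steps[0] == 5)
              + truth.gamma_exac * truth.exac_base_rate + lam)
        mu0 = x0 / (1 - truth.alpha1 - truth.alpha2)
        a_lag1 = a_lag2 = mu0
        hosp_prev = prim_prev = 0
        m_state = 0.0
        m_innov_sd = truth.exac_ar_sd * np.sqrt(max(1 - truth.exac_ar_rho ** 2, 0.0))
        for _ in range(truth.burn_in):
            shock = rng.normal()
            m_state = truth.exac_ar_rho * m_state + m_innov_sd * rng.normal()
            lograte = (np.log(truth.exac_base_rate)
                       + truth.exac_adherence_slope
                       * (np.clip(a_lag1, 0.0, 120.0) - 60.0)
                       + frailty - truth.exac_frailty_sd ** 2 / 2
                       + m_state - truth.exac_ar_sd ** 2 / 2
                       + truth.exac_state_dep * ((hosp_prev + prim_prev) >= 1)
                       + truth.exac_shock_scale * shock
                       - truth.exac_shock_scale ** 2 / 2)
            y = min(int(rng.poisson(np.exp(lograte))), truth.exac_max)
            hosp = int(rng.binomial(y, truth.hospital_share)) if y else 0
            prim = y - hosp
            u = truth.sigma_u * (truth.endo_rho * shock
                                 + np.sqrt(1 - truth.endo_rho ** 2) * rng.normal())
            saba0 = int(rng.random() < truth.saba_prob_by_step[steps[0]])
            a = (x0 - truth.gamma_exac * truth.exac_base_rate
                 + truth.gamma_exac * y + truth.beta_saba * saba0
                 + truth.beta_prior_hosp * (hosp_prev >= 1)
                 + truth.beta_prior_primary * (prim_prev >= 1)
                 + truth.beta_prior_interaction
                 * ((hosp_prev >= 1) and (prim_prev >= 1))
                 + truth.alpha1 * a_lag1 + truth.alpha2 * a_lag2 + u)
            a_lag2, a_lag1 = a_lag1, a
            hosp_prev, prim_prev = hosp, prim
        for t in range(1, T + 1):
            step = steps[t - 1]
            age = age0 + (t - 1)
            saba = int(rng.random() < truth.saba_prob_by_step[step])
            step_change = 0 if t == 1 else int(step - steps[t - 2])

            shock = rng.normal()
            m_state = truth.exac_ar_rho * m_state + m_innov_sd * rng.normal()
            lograte = (np.log(truth.exac_base_rate)
                       + truth.exac_adherence_slope
                       * (np.clip(a_lag1, 0.0, 120.0) - 60.0)
                       + frailty - truth.exac_frailty_sd ** 2 / 2
                       + m_state - truth.exac_ar_sd ** 2 / 2
                       + truth.exac_state_dep * ((hosp_prev + prim_prev) >= 1)
                       + truth.exac_shock_scale * shock
                       - truth.exac_shock_scale ** 2 / 2)
            y = min(int(rng.poisson(np.exp(lograte))), truth.exac_max)
            hosp = int(rng.binomial(y, truth.hospital_share)) if y else 0
            prim = y - hosp

            # the latent equation always carries last year's exacerbation
            # state (the burn-in seeds it); the panel records it only from
            # t = 2 on, the pre-entry year being unobservable
            lat_h, lat_p = int(hosp_prev >= 1), int(prim_prev >= 1)
            prior_h = lat_h if t > 1 else 0
            prior_p = lat_p if t > 1 else 0

            u = truth.sigma_u * (rho * shock + np.sqrt(1 - rho ** 2) * rng.normal())
            a = (truth.beta0 + truth.alpha1 * a_lag1 + truth.alpha2 * a_lag2
                 + truth.gamma_exac * y
                 + truth.beta_age * age + truth.beta_years * t
                 + truth.beta_saba * saba
                 + truth.beta_step3 * (step == 3)
                 + truth.beta_step4 * (step == 4)
                 + truth.beta_step5 * (step == 5)
                 + truth.beta_step_change * step_change
                 + truth.beta_prior_hosp * lat_h
                 + truth.beta_prior_primary * lat_p
                 + truth.beta_prior_interaction * lat_h * lat_p
                 + lam + u)
            ppr = a + (rng.normal(0.0, truth.sigma_measure)
                       if truth.sigma_measure > 0 else 0.0)

            rows.append((pid, t, gender, ppr, age, t, saba,
                         int(step == 3), int(step == 4), int(step == 5),
                         step, step_change, y, hosp, prim,
                         prior_h, prior_p, prior_h * prior_p))
            trows.append((pid, t, a, lam, step, y, hosp, prim))
            a_lag2, a_lag1 = a_lag1, a
            hosp_prev, prim_prev = hosp, prim

    panel = pd.DataFrame(rows, columns=[
        "patient_id", "t", "gender", "ppr", "age_years", "years_in_study",
        "saba_high", "step3", "step4", "step5", "bts_step", "step_change",
        "exac_total", "hospital_count", "primary_count",
        "prior_hosp", "prior_primary", "prior_interaction"])
    cohort_truth = pd.DataFrame(trows, columns=[
        "patient_id", "t", "latent_adherence", "fixed_effect", "bts_step",
        "exac_total", "hospital_count", "primary_count"])
    return panel, cohort_truth


_ICS_BY_STEP = {  # daily doses and strength (µg/actuation) per treatment step
    2: (2.0, 100.0), 3: (2.0, 200.0), 4: (4.0, 250.0), 5: (4.0, 250.0)}
_HOSP_CODES = ("J45.0", "J45.1", "J45.9", "J46")


def simulate_records(truth: TruthParameters,
                     options: RecordOptions | None = None) -> RecordCohort:
    """Emit raw source tables whose pipeline output matches the latent truth."""
    options = options or RecordOptions()
    panel, cohort_truth = simulate_panel(truth)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))

    pat_rows, rx_rows, ev_rows, ep_rows = [], [], [], []
    truth_by = dict(list(cohort_truth.groupby("patient_id", sort=False)))
    for pid, grp in panel.groupby("patient_id", sort=True):
        grp = grp.sort_values("t")
        T = len(grp)
        age0 = int(grp["age_years"].iloc[0])
        hi = options.start_year_max - T + 1
        entry = int(rng.integers(options.start_year_min, max(hi, options.start_year_min) + 1))
        birth = date(entry - age0, 1, 1)
        index_d, exit_d = date(entry, 1, 1), date(entry + T, 1, 1)
        pat_rows.append((pid, grp["gender"].iloc[0], birth.isoformat(),
                         index_d.isoformat(), exit_d.isoformat(), 0))

        tr = truth_by[pid].sort_values("t")
        for (_, obs), (_, tru) in zip(grp.iterrows(), tr.iterrows()):
            year = entry + int(obs["t"]) - 1
            y0 = date(year, 1, 1).toordinal()
            ydays = date(year + 1, 1, 1).toordinal() - y0
            step = int(obs["bts_step"])
            a = float(tru["latent_adherence"])

            # --- ICS supply ---------------------------------------------
            target = int(round(3.65 * float(np.clip(a, 0.0, 100.0))))
            dd, strength = _ICS_BY_STEP[step]
            cursor = y0
            remaining = target
            first = True
            while remaining > 0:
                if remaining >= 28:
                    dur = 28
                elif rng.random() < options.p_cross_year:
                    dur = 28      # overshoots the year end / target
                else:
                    dur = remaining
                issue = cursor
                if not first and rng.random() < options.p_early_refill:
                    issue = max(y0, cursor - int(rng.integers(5, 16)))
                blank = rng.random() < options.p_missing_duration
                rx_rows.append((pid, "ICS", date.fromordinal(issue).isoformat(),
                                1, dur * dd, dd, strength,
                                "" if blank else dur, "inhaler"))
                cursor = issue + dur
                remaining -= dur
                first = False

            # --- SABA ---------------------------------------------------
            if int(obs["saba_high"]):
                for q in range(4):
                    d = y0 + int(ydays * (q + 0.5) / 4)
                    rx_rows.append((pid, "SABA", date.fromordinal(d).isoformat(),
                                    5, 200, 12, 100.0, "", "inhaler"))
            elif rng.random() < 0.5:
                d = y0 + int(rng.integers(0, ydays))
                rx_rows.append((pid, "SABA", date.fromordinal(d).isoformat(),
                                1, 200, 2, 100.0, "", "inhaler"))

            # --- add-on controller for steps 3+ -------------------------
            if step >= 3:
                d = y0 + int(rng.integers(0, 28))
                rx_rows.append((pid, "LABA", date.fromordinal(d).isoformat(),
                                1, 60, 2, 50.0, 30, "inhaler"))

            # --- maintenance prednisolone (step 5): fails burst criteria
            if step == 5:
                for m in range(12):
                    d = y0 + int(ydays * m / 12)
                    rx_rows.append((pid, "prednisolone",
                                    date.fromordinal(d).isoformat(),
                                    120, 1, 4, 5.0, 30, "tablet"))

            # --- exacerbations ------------------------------------------
            prim = int(obs["primary_count"])
            if prim:
                dates = [y0 + int(ydays * (j + 0.5) / prim) for j in range(prim)]
                for d in dates:
                    iso = date.fromordinal(d).isoformat()
                    if step == 5:
                        # a burst would fail the annual-days criterion here;
                        # the episode is recorded as a coded event instead
                        ev_rows.append((pid, iso,
                                        "Asthma exacerbation - emergency prednisolone given"))
                    else:
                        rx_rows.append((pid, "prednisolone", iso,
                                        40, 1, 8, 5.0, 5, "tablet"))
                        if rng.random() < options.p_keyword_echo:
                            ev_rows.append((pid, iso, "Asthma exacerbation"))
            hosp = int(obs["hospital_count"])
            if hosp:
                for j in range(hosp):
                    d = y0 + int(ydays * (j + 0.25) / hosp)
                    code = _HOSP_CODES[int(rng.integers(0, len(_HOSP_CODES)))]
                    ep_rows.append((pid, date.fromordinal(d).isoformat(), code))

            if rng.random() < options.p_noise_event:
                d = y0 + int(rng.integers(0, ydays))
                ev_rows.append((pid, date.fromordinal(d).isoformat(),
                                "Asthma annual review"))

    patients = pd.DataFrame(pat_rows, columns=[
        "patient_id", "gender", "birth_date", "index_date", "exit_date", "copd_flag"])
    therapy = pd.DataFrame(rx_rows, columns=[
        "patient_id", "drug_class", "issue_date", "quantity_packs",
        "doses_per_pack", "daily_dose", "strength", "duration_days", "dosage_form"])
    clinical = pd.DataFrame(ev_rows, columns=["patient_id", "event_date", "term_text"])
    episodes = pd.DataFrame(ep_rows, columns=["patient_id", "admission_date",
                                              "primary_icd10"])
    return RecordCohort(patients, therapy, clinical, episodes, cohort_truth)


def write_record_tables(cohort: RecordCohort, outdir, schema=None) -> dict:
    """Write the four raw tables plus truth.csv using the file dialect."""
    from pathlib import Path
    from pprpanel.records import Schema

    schema = schema or Schema()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _dump(df, name, colmap):
        out = df.rename(columns=colmap)
        p = outdir / name
        out.to_csv(p, sep=schema.delimiter, index=False)
        paths[name] = p

    _dump(cohort.patients, "patient.csv", schema.patient)
    _dump(cohort.therapy, "therapy.csv", schema.therapy)
    _dump(cohort.clinical, "clinical.csv", schema.clinical)
    _dump(cohort.episodes, "hes_episodes.csv", schema.hes)
    tp = outdir / "truth.csv"
    cohort.truth.to_csv(tp, index=False, float_format="%.6f")
    paths["truth.csv"] = tp
    return paths


def truth_as_dict(truth: TruthParameters) -> dict:
    d = asdict(truth)
    d["saba_prob_by_step"] = {str(k): v for k, v in d["saba_prob_by_step"].items()}
    return d
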