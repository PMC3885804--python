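"""Patient-year clinical phenotyping: exacerbations, severity, control.

Exacerbations are identified from three sources and classified by care
setting:

* hospital-recorded: inpatient episodes whose primary ICD-10 diagnosis is
  in the asthma block (default J45.x and J46);
* primary-care managed: oral prednisolone "burst" prescriptions meeting
  duration and quantity/strength criteria (duration < 10 days per
  prescription, < 90 prednisolone days in the year, and qty ≤ 20 at 25 mg
  or qty ≤ 112 at 5 mg);
* keyword-matched coded events (term text standing in for Read-code
  descriptions), each keyword group routed to a primary- or
  secondary-care destination.

A prednisolone prescription failing the burst criteria marks the
patient-year as BTS/SIGN step 5 (maintenance oral steroids). Below step 5
the step is reconstructed from prescribing: high-dose ICS (> 800 µg/day
beclometasone-equivalent by default) plus an add-on controller (LABA/LTRA)
gives step 4, ICS + add-on gives step 3, ICS alone step 2.

Asthma control: average SABA use over 10 doses/day across the year flags
poor control.

Events within a configurable window (default 14 days) of one another are
counted as a single exacerbation episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pprpanel.ppr import build_intervals, _ord


@dataclass(frozen=True)
class ClinicalConfig:
    #: (required substrings, destination) — matched case-insensitively
    keyword_groups: tuple = (
        (("asthma", "exacerbation"), "primary"),
        (("emergency prednisolone",), "primary"),
        (("admit to hospital",), "secondary"),
    )
    icd10_prefixes: tuple = ("J45", "J46")
    burst_max_duration_days: float = 10.0    # strict <
    burst_max_annual_days: float = 90.0      # strict <
    #: strength (mg) -> maximum quantity (total tablets, inclusive)
    burst_qty_limits: dict = field(default_factory=lambda: {25.0: 20.0, 5.0: 112.0})
    high_dose_threshold_ug: float = 800.0    # strict >, daily_dose x strength
    dedup_window_days: int = 14
    saba_daily_threshold: float = 10.0       # strict >


def classify_prednisolone_burst(duration_days, annual_pred_days, qty_units,
                                strength, config: ClinicalConfig | None = None):
    """Vectorized burst rule; NaN in any needed field fails the record."""
    config = config or ClinicalConfig()
    duration_days = np.asarray(duration_days, dtype=float)
    qty_units = np.asarray(qty_units, dtype=float)
    strength = np.asarray(strength, dtype=float)
    ok_dur = duration_days < config.burst_max_duration_days
    ok_year = np.asarray(annual_pred_days, dtype=float) < config.burst_max_annual_days
    ok_qty = np.zeros(np.shape(qty_units), dtype=bool)
    for s, qmax in config.burst_qty_limits.items():
        ok_qty |= (strength == s) & (qty_units <= qmax)
    return ok_dur & ok_year & ok_qty


def match_keywords(terms, config: ClinicalConfig | None = None) -> np.ndarray:
    """Destination per term: 'primary', 'secondary' or '' (no match).

    First matching keyword group wins; matching is case-insensitive
    substring containment of every keyword in the group.
    """
    config = config or ClinicalConfig()
    out = np.full(len(terms), "", dtype=object)
    lowered = [str(t).lower() for t in terms]
    for i, text in enumerate(lowered):
        for keywords, dest in config.keyword_groups:
            if all(k.lower() in text for k in keywords):
                out[i] = dest
                break
    return out


def is_asthma_code(codes, config: ClinicalConfig | None = None) -> np.ndarray:
    config = config or ClinicalConfig()
    norm = [str(c).upper().replace(".", "") for c in codes]
    return np.array([any(c.startswith(p.replace(".", ""))
                         for p in config.icd10_prefixes) for c in norm])


def flag_saba_high_use(total_doses: float, denominator_days: float,
                       config: ClinicalConfig | None = None) -> bool:
    config = config or ClinicalConfig()
    if denominator_days <= 0:
        return False
    return total_doses / denominator_days > config.saba_daily_threshold


def _dedup_count(dates: np.ndarray, window: int) -> int:
    """Count event clusters: a date within `window` days of the cluster
    start joins that cluster."""
    if len(dates) == 0:
        return 0
    dates = np.sort(dates)
    count = 1
    cluster_start = dates[0]
    for d in dates[1:]:
        if d - cluster_start > window:
            count += 1
            cluster_start = d
    return count


def assign_bts_step(any_pred_failing: bool, has_ics: bool, high_dose: bool,
                    has_addon: bool) -> int:
    if any_pred_failing:
        return 5
    if has_ics and has_addon and high_dose:
        return 4
    if has_ics and has_addon:
        return 3
    return 2


def classify_cohort(patients: pd.DataFrame, therapy_imputed: pd.DataFrame,
                    clinical: pd.DataFrame, episodes: pd.DataFrame,
                    config: ClinicalConfig | None = None) -> pd.DataFrame:
    """Build the patient-year clinical table.

    Uses the same calendar-year intervals as the PPR engine. Returns one
    row per patient-year with exacerbation counts (total = hospital +
    primary-care + unlinked secondary-care keyword events), care-setting
    indicators, BTS/SIGN step, annual step change and the SABA
    poor-control flag.
    """
    config = config or ClinicalConfig()
    w = config.dedup_window_days

    th = therapy_imputed.copy()
    th["_ord"] = [_ord(d) for d in th["issue_date"]]
    cl = clinical.copy()
    cl["_ord"] = [_ord(d) for d in cl["event_date"]]
    cl["_dest"] = match_keywords(cl["term_text"].tolist(), config)
    ep = episodes.copy()
    ep["_ord"] = [_ord(d) for d in ep["admission_date"]]
    ep["_asthma"] = is_asthma_code(ep["primary_icd10"].tolist(), config) \
        if len(ep) else np.zeros(0, dtype=bool)

    th_by = dict(list(th.groupby("patient_id", sort=False)))
    cl_by = dict(list(cl.groupby("patient_id", sort=False)))
    ep_by = dict(list(ep.groupby("patient_id", sort=False)))

    rows = []
    for _, p in patients.iterrows():
        pid = p["patient_id"]
        intervals = build_intervals(p["index_date"], p["exit_date"])
        if intervals.empty:
            continue
        pth = th_by.get(pid, th.iloc[0:0])
        pcl = cl_by.get(pid, cl.iloc[0:0])
        pep = ep_by.get(pid, ep.iloc[0:0])
        prev_step = None
        for _, iv in intervals.iterrows():
            lo, hi = iv["start"], iv["end"]
            rx = pth[(pth["_ord"] >= lo) & (pth["_ord"] < hi)]
            pred = rx[rx["drug_class"] == "prednisolone"]
            annual_days = np.nansum(pred["duration_days"].to_numpy(dtype=float))
            qty_units = (pred["quantity_packs"].to_numpy(dtype=float)
                         * np.nan_to_num(pred["doses_per_pack"].to_numpy(dtype=float),
                                         nan=1.0))
            burst = classify_prednisolone_burst(
                pred["duration_days"], annual_days, qty_units,
                pred["strength"], config) if len(pred) else np.zeros(0, bool)
            any_fail = len(pred) > 0 and (~burst).any()

            ics = rx[rx["drug_class"] == "ICS"]
            has_ics = len(ics) > 0
            daily_ug = (ics["daily_dose"].to_numpy(dtype=float)
                        * ics["strength"].to_numpy(dtype=float))
            high_dose = bool(np.nanmax(daily_ug, initial=0.0)
                             > config.high_dose_threshold_ug)
            has_addon = bool(rx["drug_class"].isin(["LABA", "LTRA"]).any())
            step = assign_bts_step(any_fail, has_ics, high_dose, has_addon)

            saba = rx[rx["drug_class"] == "SABA"]
            saba_doses = np.nansum(saba["quantity_packs"].to_numpy(dtype=float)
                                   * saba["doses_per_pack"].to_numpy(dtype=float))
            saba_high = flag_saba_high_use(saba_doses, iv["denominator_days"], config)

            ev = pcl[(pcl["_ord"] >= lo) & (pcl["_ord"] < hi)]
            kw_primary = ev.loc[ev["_dest"] == "primary", "_ord"].to_numpy()
            kw_secondary = ev.loc[ev["_dest"] == "secondary", "_ord"].to_numpy()

            adm = pep[(pep["_ord"] >= lo) & (pep["_ord"] < hi) & pep["_asthma"]]
            hosp_count = len(adm)
            adm_dates = adm["_ord"].to_numpy()

            burst_dates = pred.loc[np.asarray(burst, dtype=bool), "_ord"].to_numpy() \
                if len(pred) else np.empty(0, np.int64)
            primary_count = _dedup_count(
                np.concatenate([burst_dates, kw_primary]), w)

            # secondary keyword events already represented by an admission
            # within the window are absorbed; the rest count toward the
            # total (not the hospital indicator)
            unlinked = [d for d in kw_secondary
                        if not (len(adm_dates) and np.min(np.abs(adm_dates - d)) <= w)]
            secondary_extra = _dedup_count(np.asarray(unlinked, dtype=np.int64), w)

            total = hosp_count + primary_count + secondary_extra
            step_change = 0 if prev_step is None else step - prev_step
            prev_step = step
            rows.append((pid, int(iv["t"]), int(iv["year"]), total,
                         hosp_count, primary_count, secondary_extra,
                         int(hosp_count >= 1), int(primary_count >= 1),
                         step, step_change, int(saba_high)))

    return pd.DataFrame(rows, columns=[
        "patient_id", "t", "year", "exacerbation_total", "hospital_count",
        "primary_count", "secondary_keyword_count", "hospital_admission",
        "primary_care_managed", "bts_step", "step_change", "saba_high"])
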