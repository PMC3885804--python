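"""Imputation of missing prescription durations.

A prescription's duration (days of supply) is frequently blank in
primary-care prescribing data. Durations are resolved by a fixed cascade:

1. the recorded duration, when present;
2. total doses prescribed (packs x doses per pack) divided by the recorded
   daily dose, rounded to the nearest integer (ties up), minimum 1 day;
3. as (2) but substituting the patient's most recent earlier daily dose for
   the same drug class when the record's own daily dose is missing;
4. as (2) but substituting the cohort median daily dose for the record's
   dosage form;
5. otherwise the record is left unresolvable (it contributes no supply
   window downstream, and under the adjusted-denominator policy opens a
   documented gap).

A daily dose of zero is treated as missing and the cascade continues. Every
record carries a provenance flag (``duration_source``) so imputation is
auditable, and records with recorded durations are never altered. Outlying
pack sizes can optionally be snapped to a per-form list of valid sizes
(standing in for formulary pack data) before step 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SOURCES = ("recorded", "doses_over_dailydose", "prior_prescription",
           "median_by_form", "unresolvable")

#: cascade step names accepted by ``disable``
CASCADE_STEPS = ("doses_over_dailydose", "prior_prescription", "median_by_form")


def build_median_daily_dose(therapy: pd.DataFrame) -> dict[str, float]:
    """Median observed daily dose per dosage form.

    Uses only records with an observed positive daily dose; the median of an
    even count is the mean of the middle two. Forms with no observed doses
    are absent from the result.
    """
    ok = therapy["daily_dose"].notna() & (therapy["daily_dose"] > 0)
    sub = therapy.loc[ok & therapy["dosage_form"].notna()]
    return sub.groupby("dosage_form")["daily_dose"].median().to_dict()


def snap_pack_sizes(doses_per_pack: pd.Series, dosage_form: pd.Series,
                    valid_sizes: dict[str, list[float]]) -> pd.Series:
    """Snap each pack size to the nearest valid size for its form."""
    out = doses_per_pack.copy()
    for form, sizes in valid_sizes.items():
        arr = np.asarray(sorted(sizes), dtype=float)
        mask = (dosage_form == form) & doses_per_pack.notna()
        if mask.any():
            vals = doses_per_pack[mask].to_numpy(dtype=float)
            idx = np.clip(np.searchsorted(arr, vals), 1, len(arr) - 1)
            lo, hi = arr[idx - 1], arr[idx]
            out[mask] = np.where(vals - lo <= hi - vals, lo, hi)
    return out


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def impute_durations(therapy: pd.DataFrame,
                     medians: dict[str, float] | None = None,
                     valid_pack_sizes: dict[str, list[float]] | None = None,
                     disable: set[str] | None = None) -> pd.DataFrame:
    """Resolve durations for a therapy frame, adding provenance.

    Parameters
    ----------
    therapy
        Validated therapy frame (see :mod:`pprpanel.records`).
    medians
        Per-form median daily doses built on the *full* cohort; computed
        here when not supplied.
    valid_pack_sizes
        Optional per-form valid pack-size lists for outlier snapping.
    disable
        Cascade steps to switch off (sensitivity runs); names from
        :data:`CASCADE_STEPS`.

    Returns a copy with ``duration_days`` filled where resolvable and a
    ``duration_source`` column.
    """
    disable = disable or set()
    df = therapy.copy()
    if medians is None:
        medians = build_median_daily_dose(df)

    duration = df["duration_days"].to_numpy(dtype=float)
    source = np.where(~np.isnan(duration), "recorded", "unresolvable").astype(object)

    packs = df["quantity_packs"].to_numpy(dtype=float)
    doses_pp = df["doses_per_pack"].to_numpy(dtype=float)
    if valid_pack_sizes:
        doses_pp = snap_pack_sizes(pd.Series(doses_pp), df["dosage_form"], valid_pack_sizes).to_numpy(dtype=float)
    total_doses = packs * doses_pp

    own_dd = df["daily_dose"].to_numpy(dtype=float)
    own_dd = np.where(own_dd <= 0, np.nan, own_dd)  # zero dose treated as missing

    # most recent earlier observed daily dose, per patient and drug class
    order = df.sort_values(["patient_id", "drug_class", "issue_date"],
                           kind="mergesort").index
    ordered = pd.Series(own_dd, index=df.index).reindex(order)
    keys = [df["patient_id"].reindex(order), df["drug_class"].reindex(order)]
    prior = ordered.groupby(keys).ffill().groupby(keys).shift(1)
    prior_dd = prior.reindex(df.index).to_numpy(dtype=float)

    median_dd = df["dosage_form"].map(medians).to_numpy(dtype=float)

    need = np.isnan(duration)
    for dd, label in ((own_dd, "doses_over_dailydose"),
                      (prior_dd, "prior_prescription"),
                      (median_dd, "median_by_form")):
        if label in disable:
            continue
        if label != "doses_over_dailydose" and "doses_over_dailydose" in disable:
            continue  # steps 3-4 reuse the doses/dailydose formula
        usable = need & ~np.isnan(total_doses) & (total_doses > 0) & ~np.isnan(dd)
        vals = np.maximum(_round_half_up(total_doses[usable] / dd[usable]), 1.0)
        duration[usable] = vals
        source[usable] = label
        need = np.isnan(duration)

    df["duration_days"] = duration
    df["duration_source"] = source
    return df


def imputation_audit(imputed: pd.DataFrame) -> pd.DataFrame:
    """One row per record: position, patient, source flag."""
    return pd.DataFrame({
        "record": np.arange(1, len(imputed) + 1),
        "patient_id": imputed["patient_id"].to_numpy(),
        "duration_source": imputed["duration_source"].to_numpy(),
    })
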