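"""Assembly of the estimation panel from PPR and clinical tables.

One row per patient-year carrying the modelled adherence measure
(strategy-5 PPR), its two lags, and the regressors: age, years in study,
SABA poor-control flag, treatment-step dummies (step 2 is the baseline),
annual step change, current-year exacerbation total, and prior-year
care-setting indicators with their interaction.

Lags are computed within patient over *consecutive* periods only — a gap
year breaks the lag chain, because the autoregressive coefficients are
one-year dynamics. An observation is estimable when both lags exist;
patients contributing no estimable observation are dropped entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PANEL_COLUMNS = [
    "patient_id", "t", "year", "gender", "ppr", "ppr_lag1", "ppr_lag2",
    "age_years", "years_in_study", "saba_high", "step3", "step4", "step5",
    "step_change", "exac_total", "prior_hosp", "prior_primary",
    "prior_interaction", "estimable",
]


def add_lags(df: pd.DataFrame, col: str = "ppr", lags: int = 2) -> pd.DataFrame:
    """Within-patient lag columns over consecutive t; gaps yield NaN."""
    out = df.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)
    g = out.groupby("patient_id", sort=False)
    tdiff = {k: g["t"].shift(k) for k in range(1, lags + 1)}
    for k in range(1, lags + 1):
        lag = g[col].shift(k)
        consecutive = (out["t"] - tdiff[k]) == k
        out[f"{col}_lag{k}"] = lag.where(consecutive)
    return out


def assemble_panel(ppr_long: pd.DataFrame, clinical: pd.DataFrame,
                   patients: pd.DataFrame, strategy: int = 5) -> pd.DataFrame:
    """Merge the PPR and clinical patient-year tables into the panel.

    ``ppr_long`` is the long table from :func:`pprpanel.ppr.compute_cohort_ppr`
    (the ``strategy`` slice is used as the dependent variable). Raises on
    duplicate (patient, t) keys. Patients with no estimable observation
    (fewer than three consecutive recorded years) are dropped.
    """
    dep = ppr_long[ppr_long["strategy"] == strategy]
    dep = dep[["patient_id", "t", "year", "start", "ppr"]]
    for name, frame in (("ppr", dep), ("clinical", clinical)):
        dups = frame.duplicated(["patient_id", "t"])
        if dups.any():
            raise ValueError(
                f"duplicate (patient_id, t) keys in {name} table: "
                f"{frame.loc[dups, ['patient_id', 't']].head().to_dict('records')}")

    df = dep.merge(clinical.drop(columns=["year"], errors="ignore"),
                   on=["patient_id", "t"], how="inner")
    df = df.merge(patients[["patient_id", "gender", "birth_date"]],
                  on="patient_id", how="left")

    df = df.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)
    birth_ord = pd.to_datetime(df["birth_date"]).map(pd.Timestamp.toordinal)
    df["age_years"] = np.floor((df["start"] - birth_ord) / 365.25).astype(int)
    df["years_in_study"] = df["t"]
    for s in (3, 4, 5):
        df[f"step{s}"] = (df["bts_step"] == s).astype(int)

    g = df.groupby("patient_id", sort=False)
    consec1 = (df["t"] - g["t"].shift(1)) == 1
    df["prior_hosp"] = g["hospital_admission"].shift(1).where(consec1).fillna(0).astype(int)
    df["prior_primary"] = g["primary_care_managed"].shift(1).where(consec1).fillna(0).astype(int)
    df["prior_interaction"] = df["prior_hosp"] * df["prior_primary"]
    df = df.rename(columns={"exacerbation_total": "exac_total"})

    df = add_lags(df, "ppr", lags=2)
    df["estimable"] = df["ppr_lag1"].notna() & df["ppr_lag2"].notna()
    keep = df.groupby("patient_id")["estimable"].transform("any")
    df = df[keep].reset_index(drop=True)
    return df[PANEL_COLUMNS]


def prepare_direct_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Add lags/estimability to a directly simulated panel."""
    df = add_lags(panel, "ppr", lags=2)
    df["estimable"] = df["ppr_lag1"].notna() & df["ppr_lag2"].notna()
    keep = df.groupby("patient_id")["estimable"].transform("any")
    return df[keep].reset_index(drop=True)


def stratify(panel: pd.DataFrame, by: str = "gender") -> dict[str, pd.DataFrame]:
    """Disjoint, exhaustive split of the panel on one attribute."""
    if by not in panel.columns:
        raise ValueError(f"unknown stratification attribute {by!r}")
    return {str(k): g.reset_index(drop=True) for k, g in panel.groupby(by, sort=True)}
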