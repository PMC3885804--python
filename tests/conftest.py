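import numpy as np
import pandas as pd
import pytest

from pprpanel.impute import impute_durations
from pprpanel.ppr import compute_cohort_ppr
from pprpanel.clinical import classify_cohort
from pprpanel.panel import assemble_panel
from pprpanel.synth import TruthParameters, RecordOptions, simulate_records


@pytest.fixture(scope="session")
def record_cohort():
    """Small record-mode cohort exercised by several suites."""
    truth = TruthParameters(n_patients=60, seed=11)
    return simulate_records(truth, RecordOptions())


@pytest.fixture(scope="session")
def clean_record_cohort():
    """Record mode with overlap / missingness / cross-year emission off."""
    truth = TruthParameters(n_patients=500, seed=13)
    opts = RecordOptions(p_early_refill=0.0, p_cross_year=0.0,
                         p_missing_duration=0.0)
    return simulate_records(truth, opts)


@pytest.fixture(scope="session")
def pipeline_outputs(record_cohort):
    """therapy_imputed, ppr table, clinical table, panel for the small cohort."""
    cohort = record_cohort
    # dates in generated tables are ISO strings; parse once here
    patients = cohort.patients.assign(
        index_date=pd.to_datetime(cohort.patients["index_date"]),
        exit_date=pd.to_datetime(cohort.patients["exit_date"]),
        birth_date=pd.to_datetime(cohort.patients["birth_date"]))
    therapy = cohort.therapy.assign(
        issue_date=pd.to_datetime(cohort.therapy["issue_date"]),
        duration_days=pd.to_numeric(cohort.therapy["duration_days"],
                                    errors="coerce"))
    clinical = cohort.clinical.assign(
        event_date=pd.to_datetime(cohort.clinical["event_date"]))
    episodes = cohort.episodes.assign(
        admission_date=pd.to_datetime(cohort.episodes["admission_date"]))

    imputed = impute_durations(therapy)
    ppr_long, _ = compute_cohort_ppr(patients, imputed)
    clin = classify_cohort(patients, imputed, clinical, episodes)
    panel = assemble_panel(ppr_long, clin, patients)
    return {"patients": patients, "imputed": imputed, "ppr": ppr_long,
            "clinical": clin, "panel": panel, "truth": cohort.truth}


def parse_cohort_dates(cohort):
    """Typed copies of the four generated tables (ISO strings -> timestamps)."""
    patients = cohort.patients.assign(
        index_date=pd.to_datetime(cohort.patients["index_date"]),
        exit_date=pd.to_datetime(cohort.patients["exit_date"]),
        birth_date=pd.to_datetime(cohort.patients["birth_date"]))
    therapy = cohort.therapy.assign(
        issue_date=pd.to_datetime(cohort.therapy["issue_date"]),
        duration_days=pd.to_numeric(cohort.therapy["duration_days"],
                                    errors="coerce"))
    clinical = cohort.clinical.assign(
        event_date=pd.to_datetime(cohort.clinical["event_date"]))
    episodes = cohort.episodes.assign(
        admission_date=pd.to_datetime(cohort.episodes["admission_date"]))
    return patients, therapy, clinical, episodes
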