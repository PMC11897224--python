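import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from metpath.config import RunConfig
from metpath.synth import SimulationDesign, simulate_study


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_study():
    """A small complete synthetic study used across modules."""
    design = SimulationDesign(n_people=300, n_pathways=4,
                              metabolites_per_pathway=10, n_unannotated=5,
                              n_xenobiotics=10, seed=11)
    return simulate_study(design)


@pytest.fixture(scope="session")
def default_study():
    """The reference recovery-design study (one seed)."""
    return simulate_study(SimulationDesign(seed=5))


SAMPLE_DATE = pd.Timestamp("2010-06-15")


def _ev(pid, kind, code, date, sys=np.nan, dia=np.nan):
    return {"person_id": pid, "kind": kind, "code": code,
            "date": pd.Timestamp(date), "systolic": sys, "diastolic": dia}


def truth_table_histories():
    """Constructed EHR histories covering every classification rule and
    boundary, with the enumerated expected class per person.

    Sample date is 2010-06-15 for everyone; the six-month rule is 183 days.
    """
    H: list[tuple[str, list[dict], str]] = []

    def add(tag, events, expected):
        H.append((tag, events, expected))

    # --- case rule (a): two diagnoses, six-month span boundary ---
    add("span_183_exact", [_ev("", "diagnosis", "I10", "2012-01-01"),
                           _ev("", "diagnosis", "I10", "2012-07-02")],
        "incident_case")                                   # 183 days: >= holds
    add("span_182_short", [_ev("", "diagnosis", "I10", "2012-01-01"),
                           _ev("", "diagnosis", "I10", "2012-07-01")],
        "control")                                         # two dx < 6 months, no other signal
    add("span_184", [_ev("", "diagnosis", "I10", "2012-01-01"),
                     _ev("", "diagnosis", "I10", "2012-07-03")],
        "incident_case")
    add("span_two_codes", [_ev("", "diagnosis", "I10", "2012-01-01"),
                           _ev("", "diagnosis", "I12.9", "2013-01-01")],
        "incident_case")
    # --- case rule (b): diagnosis + prescription, any order ---
    add("dx_plus_rx", [_ev("", "diagnosis", "I10", "2012-01-01"),
                       _ev("", "diagnosis", "I10", "2012-05-01"),
                       _ev("", "prescription", "C03AA03", "2012-02-01")],
        "incident_case")
    add("rx_before_dx", [_ev("", "prescription", "C09AA02", "2011-01-01"),
                         _ev("", "diagnosis", "I11.0", "2012-03-01")],
        "incident_case")
    add("subcode_prefix", [_ev("", "diagnosis", "I10.9", "2012-01-01"),
                           _ev("", "prescription", "C07AB02", "2012-06-01")],
        "incident_case")
    # --- prevalent vs incident split ---
    add("dx_before_sample", [_ev("", "diagnosis", "I10", "2009-01-01"),
                             _ev("", "prescription", "C07AB02", "2012-01-01")],
        "prevalent_case")
    add("dx_on_sample_day", [_ev("", "diagnosis", "I10", "2010-06-15"),
                             _ev("", "diagnosis", "I10", "2011-02-01")],
        "prevalent_case")                                  # on the draw day -> prevalent
    add("dx_day_after_sample", [_ev("", "diagnosis", "I10", "2010-06-16"),
                                _ev("", "diagnosis", "I10", "2011-02-01")],
        "incident_case")
    add("first_dx_dates_case", [_ev("", "diagnosis", "I13", "2008-01-01"),
                                _ev("", "diagnosis", "I10", "2012-01-01")],
        "prevalent_case")                                  # earliest dx is the case date
    # --- uncertain: single diagnosis ---
    add("single_dx", [_ev("", "diagnosis", "I10", "2012-01-01")], "uncertain")
    add("single_dx_subcode", [_ev("", "diagnosis", "I13.9", "2012-01-01")],
        "uncertain")
    add("single_dx_dup_rows", [_ev("", "diagnosis", "I10", "2012-01-01"),
                               _ev("", "diagnosis", "I10", "2012-01-01")],
        "uncertain")                                       # duplicates: one date
    # --- uncertain: adjacent codes ---
    add("pregnancy_O13", [_ev("", "diagnosis", "O13", "2012-01-01")], "uncertain")
    add("elevated_reading_R030", [_ev("", "diagnosis", "R03.0", "2012-01-01")],
        "uncertain")
    add("retinopathy_H350", [_ev("", "diagnosis", "H35.0", "2012-01-01")],
        "uncertain")
    add("encephalopathy_I674", [_ev("", "diagnosis", "I67.4", "2012-01-01")],
        "uncertain")
    add("secondary_I15", [_ev("", "diagnosis", "I15.0", "2012-01-01")], "uncertain")
    # --- uncertain: blood-pressure cut-offs (strict 'over') ---
    add("bp_141_80", [_ev("", "bp_measurement", "", "2010-06-15", 141, 80)],
        "uncertain")
    add("bp_140_91", [_ev("", "bp_measurement", "", "2010-06-15", 140, 91)],
        "uncertain")
    add("bp_140_90_exact", [_ev("", "bp_measurement", "", "2010-06-15", 140, 90)],
        "control")
    add("bp_139_89", [_ev("", "bp_measurement", "", "2010-06-15", 139, 89)],
        "control")
    # --- exclude and controls ---
    add("no_events", [], "exclude")
    add("rx_only", [_ev("", "prescription", "C03AA03", "2012-01-01")], "control")
    add("unrelated_dx", [_ev("", "diagnosis", "J06.9", "2012-01-01")], "control")
    add("bp_and_rx_no_dx", [_ev("", "bp_measurement", "", "2010-06-15", 150, 85),
                            _ev("", "prescription", "C03AA03", "2012-01-01")],
        "uncertain")                                       # elevated bp dominates rx-only
    # --- precedence: case beats uncertain signals ---
    add("case_beats_O14", [_ev("", "diagnosis", "I10", "2012-01-01"),
                           _ev("", "diagnosis", "I10", "2012-08-01"),
                           _ev("", "diagnosis", "O14", "2012-02-01")],
        "incident_case")
    add("case_with_I15", [_ev("", "diagnosis", "I15", "2011-01-01"),
                          _ev("", "diagnosis", "I10", "2012-01-01"),
                          _ev("", "diagnosis", "I10", "2012-08-01")],
        "incident_case")
    add("single_dx_plus_high_bp", [_ev("", "diagnosis", "I10", "2012-01-01"),
                                   _ev("", "bp_measurement", "", "2010-06-15",
                                       155, 95)],
        "uncertain")
    return H


@pytest.fixture(scope="session")
def truth_table():
    """(events, covariates, expected assignments) for the rule fixture."""
    histories = truth_table_histories()
    ev_rows, cov_rows, expected = [], [], []
    for i, (tag, events, klass) in enumerate(histories):
        pid = f"T{i:03d}_{tag}"
        for e in events:
            e = dict(e)
            e["person_id"] = pid
            ev_rows.append(e)
        cov_rows.append({
            "person_id": pid, "sex": "female", "bmi": 25.0, "smoking": "never",
            "education": "high", "residency": "city", "time_of_day": "before10",
            "birth_date": pd.Timestamp("1960-01-01"), "sample_date": SAMPLE_DATE,
            "death_date": pd.NaT, "followup_end": pd.Timestamp("2021-12-31"),
        })
        expected.append({"person_id": pid, "expected": klass})
    events_df = pd.DataFrame(
        ev_rows, columns=["person_id", "kind", "code", "date",
                          "systolic", "diastolic"])
    return events_df, pd.DataFrame(cov_rows), pd.DataFrame(expected)
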