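"""Rule-based EHR phenotyping of hypertension.

Every person is assigned exactly one class:

* **case** — at least two hypertension diagnoses (I10–I13) spanning at
  least six months (183 days), or one hypertension diagnosis plus an
  antihypertensive prescription (ATC C02–C09), in any temporal order. The
  first hypertension diagnosis dates the case; cases diagnosed on or before
  the sample date are *prevalent*, later ones *incident*.
* **uncertain** — a single hypertension diagnosis with no other signal; a
  hypertension-adjacent code (pregnancy hypertensive disorders O10–O16,
  elevated reading R03.0, hypertensive retinopathy H35.0, hypertensive
  encephalopathy I67.4, secondary hypertension I15); or a blood-pressure
  measurement strictly above 140 mmHg systolic or 90 mmHg diastolic.
* **exclude** — no EHR events of any kind.
* **control** — none of the above.

Case criteria take precedence over uncertain codes: a person with two
qualifying diagnoses is a case even if they also carry, say, an O13 code.
Prescription-only persons (ATC match, no hypertension diagnosis) are
eligible controls; their count is logged. ICD-10/ATC matching is by prefix
on dot-stripped upper-cased codes ("I10.9" matches "I10").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .datatypes import validate_events

log = logging.getLogger(__name__)

#: Hypertension-adjacent codes that mark a person "uncertain" (dot-stripped).
UNCERTAIN_ICD_PREFIXES = (
    "O10", "O11", "O13", "O14", "O15", "O16", "R030", "H350", "I674", "I15",
)


def _norm(code: str) -> str:
    return str(code).replace(".", "").upper()


def _matches(code: str, prefixes: tuple[str, ...]) -> bool:
    c = _norm(code)
    return any(c.startswith(_norm(p)) for p in prefixes)


def _htn_diagnoses(events: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    d = events[events["kind"] == "diagnosis"]
    mask = d["code"].map(lambda c: _matches(c, cfg.hypertension_icd)).astype(bool)
    return d[mask]


def is_case(events: pd.DataFrame, cfg: RunConfig) -> tuple[bool, pd.Timestamp | None]:
    """Case test for one person's (date-sorted) events.

    Returns (is_case, date of the earliest hypertension diagnosis).
    """
    dx = _htn_diagnoses(events, cfg)
    if len(dx) == 0:
        return False, None
    first = dx["date"].min()
    dates = dx["date"].drop_duplicates()
    span_ok = len(dates) >= 2 and (dates.max() - dates.min()).days >= cfg.six_months_days
    rx_mask = ((events["kind"] == "prescription")
               & events["code"].map(
                   lambda c: _matches(c, cfg.antihypertensive_atc)).astype(bool))
    rx = events[rx_mask]
    if span_ok or len(rx) > 0:
        return True, first
    return False, None


def is_uncertain(events: pd.DataFrame, cfg: RunConfig) -> tuple[bool, str]:
    """Uncertain test, applied only after ``is_case`` returned False."""
    dx = _htn_diagnoses(events, cfg)
    if dx["date"].nunique() == 1:
        return True, "single_diagnosis"
    diag = events[events["kind"] == "diagnosis"]
    if diag["code"].map(lambda c: _matches(c, UNCERTAIN_ICD_PREFIXES)).astype(bool).any():
        return True, "uncertain_code"
    bp = events[events["kind"] == "bp_measurement"]
    if ((bp["systolic"] > cfg.bp_sys_cut) | (bp["diastolic"] > cfg.bp_dia_cut)).any():
        return True, "elevated_bp"
    return False, ""


@dataclass
class PhenotypeSummary:
    counts: dict[str, int]
    n_prescription_only_controls: int


def classify(
    events: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Assign every covariate person a phenotype class.

    Returns a DataFrame (person_id, klass, first_qualifying_date,
    rule_fired). Precedence: case -> uncertain -> exclude -> control; cases
    split into prevalent (first qualifying diagnosis on or before the
    sample date) and incident. Persons with events but no covariate row
    raise, persons with a covariate row but no events are excluded.
    """
    events = validate_events(events)
    persons = set(covariates["person_id"])
    orphan = set(events["person_id"]) - persons
    if orphan:
        raise ValueError(f"persons in events but not in covariates: {sorted(orphan)}")
    pid_col = covariates["person_id"]
    sample_date = covariates.set_index("person_id")["sample_date"]

    code_norm = events["code"].astype(str).str.replace(".", "", regex=False).str.upper()
    htn_pfx = tuple(_norm(p) for p in cfg.hypertension_icd)
    atc_pfx = tuple(_norm(p) for p in cfg.antihypertensive_atc)
    unc_pfx = tuple(_norm(p) for p in UNCERTAIN_ICD_PREFIXES)
    is_dx = events["kind"] == "diagnosis"
    htn_mask = is_dx & code_norm.str.startswith(htn_pfx)
    unc_mask = is_dx & code_norm.str.startswith(unc_pfx)
    rx_mask = (events["kind"] == "prescription") & code_norm.str.startswith(atc_pfx)
    hi_bp = (events["kind"] == "bp_measurement") & (
        (events["systolic"] > cfg.bp_sys_cut) | (events["diastolic"] > cfg.bp_dia_cut))

    pid = events["person_id"]
    htn = events.loc[htn_mask].groupby("person_id")["date"]
    agg = pd.DataFrame({
        "n_htn_dates": htn.nunique(),
        "htn_min": htn.min(),
        "htn_max": htn.max(),
    }).reindex(pid_col).set_axis(pid_col.index)
    agg["n_htn_dates"] = agg["n_htn_dates"].fillna(0).astype(int)
    def by(mask: pd.Series) -> np.ndarray:
        agg_any = mask.groupby(pid).any().reindex(pid_col)
        return agg_any.to_numpy(dtype=object) == True  # noqa: E712 (NaN -> False)
    has_rx = by(rx_mask)
    has_unc_code = by(unc_mask)
    has_hi_bp = by(hi_bp)
    n_events = pid.value_counts().reindex(pid_col).fillna(0).to_numpy(int)

    span = (agg["htn_max"] - agg["htn_min"]).dt.days.fillna(0).to_numpy()
    n_dates = agg["n_htn_dates"].to_numpy()
    case = ((n_dates >= 2) & (span >= cfg.six_months_days)) | ((n_dates >= 1) & has_rx)
    sample = sample_date.reindex(pid_col).to_numpy()
    first = agg["htn_min"].to_numpy()
    prevalent = case & (first <= sample)

    klass = np.select(
        [prevalent, case, n_dates == 1, has_unc_code, has_hi_bp, n_events == 0],
        ["prevalent_case", "incident_case", "uncertain", "uncertain",
         "uncertain", "exclude"],
        default="control",
    )
    rule = np.select(
        [prevalent, case, n_dates == 1, has_unc_code, has_hi_bp, n_events == 0],
        ["case_before_sample", "case_after_sample", "single_diagnosis",
         "uncertain_code", "elevated_bp", "no_ehr_events"],
        default="none_of_the_above",
    )
    n_rx_only = int((has_rx & (klass == "control")).sum())
    out = pd.DataFrame({
        "person_id": pid_col.to_numpy(),
        "klass": klass,
        "first_qualifying_date": pd.Series(
            np.where(case, first, np.datetime64("NaT")), dtype="datetime64[ns]"),
        "rule_fired": rule,
    })
    counts = out["klass"].value_counts().to_dict()
    log.info("phenotype classes: %s; prescription-only controls: %d",
             counts, n_rx_only)
    return out


def analysis_subset(assignments: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Analysable strata: (incident case ids, control ids).

    Prevalent, uncertain and excluded persons are dropped; the counts are
    logged and reconcile with the input size.
    """
    counts = assignments["klass"].value_counts().to_dict()
    incident = assignments.loc[assignments["klass"] == "incident_case",
                               "person_id"].tolist()
    controls = assignments.loc[assignments["klass"] == "control",
                               "person_id"].tolist()
    if not incident or not controls:
        raise ValueError(
            f"empty analysable stratum (incident={len(incident)}, "
            f"controls={len(controls)}); class counts: {counts}"
        )
    log.info("analysis subset: %d incident, %d controls (dropped: %s)",
             len(incident), len(controls),
             {k: v for k, v in counts.items()
              if k not in ("incident_case", "control")})
    return incident, controls
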