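"""Matrix cleaning: missingness filters, duplicate-sample resolution,
half-minimum imputation and the natural-log transform.

Fixed stage order: metabolite filter -> person filter -> duplicate
resolution -> half-min imputation -> log. Both missingness filters use
strict-greater semantics ("more than 20%", "over 50%"); half-minimum
imputation replaces each missing cell with half the minimum observed value
of that metabolite, the standard convention for left-censored
(below-detection) intensities, and runs on the normalised pre-log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MetaboliteMatrix

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    stage: str
    n_metabolites_in: int
    n_metabolites_out: int
    n_people_in: int
    n_people_out: int
    dropped_metabolite_ids: list[str] = field(default_factory=list)
    dropped_person_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_metabolites_in - len(self.dropped_metabolite_ids) != self.n_metabolites_out:
            raise ValueError("metabolite counts do not reconcile with dropped ids")
        if self.n_people_in - len(self.dropped_person_ids) != self.n_people_out:
            raise ValueError("person counts do not reconcile with dropped ids")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_metabolites_in": self.n_metabolites_in,
            "n_metabolites_out": self.n_metabolites_out,
            "n_people_in": self.n_people_in,
            "n_people_out": self.n_people_out,
            "dropped_metabolite_ids": list(self.dropped_metabolite_ids),
            "dropped_person_ids": [list(t) for t in self.dropped_person_ids],
        }


def filter_metabolite_missingness(
    m: MetaboliteMatrix, max_frac: float
) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Drop metabolites missing in strictly more than ``max_frac`` of people."""
    if not 0 < max_frac < 1:
        raise ValueError("max_frac must lie in (0, 1)")
    if m.values.size == 0:
        raise ValueError("empty metabolite matrix")
    frac = m.values.isna().mean(axis=0)
    dropped = list(frac.index[frac > max_frac])
    kept = m.values.drop(columns=dropped)
    report = PreprocessReport(
        stage="metabolite_missingness",
        n_metabolites_in=m.values.shape[1], n_metabolites_out=kept.shape[1],
        n_people_in=m.values.shape[0], n_people_out=m.values.shape[0],
        dropped_metabolite_ids=dropped,
    )
    log.info("metabolite filter: %d -> %d", report.n_metabolites_in,
             report.n_metabolites_out)
    return MetaboliteMatrix(kept, m.sample_datetime), report


def filter_person_missingness(
    m: MetaboliteMatrix, max_frac: float
) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Drop persons missing strictly more than ``max_frac`` of metabolites."""
    if not 0 < max_frac < 1:
        raise ValueError("max_frac must lie in (0, 1)")
    if m.values.size == 0:
        raise ValueError("empty metabolite matrix")
    frac = m.values.isna().mean(axis=1)
    dropped = list(frac.index[frac > max_frac])
    kept = m.values.drop(index=dropped)
    report = PreprocessReport(
        stage="person_missingness",
        n_metabolites_in=m.values.shape[1], n_metabolites_out=m.values.shape[1],
        n_people_in=m.values.shape[0], n_people_out=kept.shape[0],
        dropped_person_ids=[(p, "person_missingness") for p in dropped],
    )
    return MetaboliteMatrix(kept, m.sample_datetime.drop(index=dropped)), report


def resolve_duplicates(
    m: MetaboliteMatrix, person_key: dict[str, str] | None = None
) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Keep one row per person: the chronologically earliest sample.

    ``person_key`` maps sample (row) ids to person ids when repeat samples
    carry distinct row ids; by default rows are already person-keyed and
    this is the identity transform.
    """
    key = pd.Series({rid: (person_key or {}).get(rid, rid) for rid in m.values.index})
    dropped: list[tuple[str, str]] = []
    keep_rows: list[str] = []
    for _, rows in key.groupby(key):
        rids = list(rows.index)
        if len(rids) == 1:
            keep_rows.append(rids[0])
            continue
        dts = m.sample_datetime.loc[rids]
        if dts.duplicated().any():
            raise ValueError(
                f"undecidable duplicate: identical sample timestamps for rows {rids}"
            )
        earliest = dts.idxmin()
        keep_rows.append(earliest)
        dropped.extend((rid, "duplicate_later_sample") for rid in rids if rid != earliest)
    keep_rows = [rid for rid in m.values.index if rid in set(keep_rows)]
    values = m.values.loc[keep_rows]
    values.index = pd.Index([key[rid] for rid in keep_rows], name=m.values.index.name)
    sample_dt = m.sample_datetime.loc[keep_rows]
    sample_dt.index = values.index
    report = PreprocessReport(
        stage="duplicate_resolution",
        n_metabolites_in=m.values.shape[1], n_metabolites_out=m.values.shape[1],
        n_people_in=m.values.shape[0], n_people_out=values.shape[0],
        dropped_person_ids=dropped,
    )
    return MetaboliteMatrix(values, sample_dt), report


def impute_half_min(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace each missing cell with half the metabolite's observed minimum."""
    all_missing = m.values.isna().all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"all-missing metabolites (filter first): {list(all_missing.index[all_missing])}"
        )
    fill = m.values.min(axis=0, skipna=True) * 0.5
    values = m.values.fillna(fill)
    return MetaboliteMatrix(values, m.sample_datetime)


def log_transform(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Natural-log transform; every value must be strictly positive."""
    arr = m.values.to_numpy()
    bad = np.argwhere(~(arr > 0) | np.isnan(arr))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-positive or missing value at person {m.values.index[r]!r}, "
            f"metabolite {m.values.columns[c]!r}; impute before log transform"
        )
    return MetaboliteMatrix.unchecked(np.log(m.values), m.sample_datetime)


def complete_case_covariates(
    cov: pd.DataFrame, required: tuple[str, ...] = ("bmi", "smoking", "time_of_day")
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop persons with any missing required covariate (complete-case rule)."""
    mask = cov[list(required)].isna().any(axis=1)
    dropped = cov.loc[mask, "person_id"].tolist()
    kept = cov.loc[~mask].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("no analysable persons after complete-case filtering")
    report = PreprocessReport(
        stage="covariate_complete_case",
        n_metabolites_in=0, n_metabolites_out=0,
        n_people_in=len(cov), n_people_out=len(kept),
        dropped_person_ids=[(p, "covariate_missing") for p in dropped],
    )
    log.info("complete-case covariates: %d -> %d persons", len(cov), len(kept))
    return kept, report


def run_preprocess(
    m: MetaboliteMatrix,
    metabolite_missing_max: float = 0.20,
    person_missing_max: float = 0.50,
    person_key: dict[str, str] | None = None,
) -> tuple[MetaboliteMatrix, list[PreprocessReport]]:
    """Full cleaning pipeline in the fixed stage order; returns log-scale matrix."""
    reports: list[PreprocessReport] = []
    m, rep = filter_metabolite_missingness(m, metabolite_missing_max)
    reports.append(rep)
    m, rep = filter_person_missingness(m, person_missing_max)
    reports.append(rep)
    m, rep = resolve_duplicates(m, person_key)
    reports.append(rep)
    m = impute_half_min(m)
    m = log_transform(m)
    return m, reports
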