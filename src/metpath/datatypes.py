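"""Shared in-memory containers for the pipeline.

Tabular inputs (annotation, pathway definitions, EHR events, covariates)
travel as validated pandas DataFrames; the metabolite matrix carries its own
missingness semantics and per-person sample timestamps, so it gets a thin
wrapper class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EHR_KINDS = ("diagnosis", "prescription", "bp_measurement")

COVARIATE_LEVELS = {
    "sex": ("male", "female"),
    "smoking": ("never", "former", "current"),
    "education": ("low", "intermediate", "high"),
    "residency": ("rural", "town", "city", "unknown"),
    "time_of_day": ("before10", "h10to15", "after15"),
}

#: Reference level of each categorical covariate in the Cox design matrix.
REFERENCE_LEVELS = {
    "sex": "male",
    "smoking": "never",
    "education": "low",
    "residency": "rural",
    "time_of_day": "before10",
}

PHENOTYPE_CLASSES = (
    "prevalent_case", "incident_case", "uncertain", "exclude", "control",
)


class MetaboliteMatrix:
    """Individuals x metabolites abundance table.

    ``values`` is a float DataFrame (rows: person ids, columns: metabolite
    ids) with NaN for missing cells; intensities are non-negative where
    present. ``sample_datetime`` gives the blood-draw timestamp per person.
    """

    def __init__(self, values: pd.DataFrame, sample_datetime: pd.Series):
        self.values = values.astype(float)
        self.sample_datetime = pd.to_datetime(sample_datetime)
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate person ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dups}")
        arr = self.values.to_numpy()
        neg = np.argwhere(arr < 0)
        if neg.size:
            r, c = neg[0]
            raise ValueError(
                f"negative intensity at person {idx[r]!r}, metabolite {cols[c]!r}"
            )
        missing_dt = set(idx) - set(self.sample_datetime.index)
        if missing_dt:
            raise ValueError(f"persons without sample_datetime: {sorted(missing_dt)}")
        if self.sample_datetime.isna().reindex(idx).any():
            bad = self.sample_datetime.reindex(idx)
            raise ValueError(
                "missing sample_datetime for persons: "
                f"{sorted(bad[bad.isna()].index.tolist())}"
            )
        self.sample_datetime = self.sample_datetime.reindex(idx)

    @classmethod
    def unchecked(cls, values: pd.DataFrame, sample_datetime: pd.Series
                  ) -> "MetaboliteMatrix":
        """Construct without the non-negativity check (log-scale matrices)."""
        m = cls.__new__(cls)
        m.values = values.astype(float)
        m.sample_datetime = pd.to_datetime(sample_datetime).reindex(values.index)
        return m

    @property
    def person_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.values.copy(), self.sample_datetime.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MetaboliteMatrix({len(self.person_ids)} persons x "
            f"{len(self.metabolite_ids)} metabolites, {self.n_missing} missing)"
        )


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a metabolite annotation table.

    Columns: metabolite_id, name, kegg_compound_id (may be empty/NaN),
    superpathway, xenobiotic_origin in {chemical, microbial, none}.
    """
    required = ["metabolite_id", "name", "kegg_compound_id",
                "superpathway", "xenobiotic_origin"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if ann["metabolite_id"].duplicated().any():
        dups = ann.loc[ann["metabolite_id"].duplicated(), "metabolite_id"].tolist()
        raise ValueError(f"duplicate metabolite ids in annotation: {dups}")
    kegg = ann["kegg_compound_id"].dropna()
    kegg = kegg[kegg.astype(str).str.len() > 0]
    bad = kegg[~kegg.astype(str).str.fullmatch(r"C\d{5}")]
    if len(bad):
        raise ValueError(f"malformed KEGG compound ids: {bad.tolist()}")
    bad_origin = set(ann["xenobiotic_origin"].dropna()) - {"chemical", "microbial", "none"}
    if bad_origin:
        raise ValueError(f"unknown xenobiotic_origin values: {sorted(bad_origin)}")
    return ann


def validate_pathway_definitions(defs: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format pathway definition table.

    Columns: pathway_id (hsaNNNNN), name, kegg_compound_id — one row per
    (pathway, compound) membership.
    """
    required = ["pathway_id", "name", "kegg_compound_id"]
    missing = [c for c in required if c not in defs.columns]
    if missing:
        raise ValueError(f"pathway table missing columns: {missing}")
    if len(defs) == 0:
        raise ValueError("pathway definition table is empty")
    bad = defs.loc[~defs["pathway_id"].astype(str).str.fullmatch(r"hsa\d{5}"),
                   "pathway_id"]
    if len(bad):
        raise ValueError(f"malformed pathway ids: {sorted(set(bad))}")
    sizes = defs.groupby("pathway_id")["kegg_compound_id"].nunique()
    empty = sizes[sizes == 0].index.tolist()
    if empty:
        raise ValueError(f"pathways with no compounds: {empty}")
    return defs


def pathway_compound_sets(defs: pd.DataFrame) -> dict[str, set[str]]:
    """pathway_id -> set of member KEGG compound ids."""
    validate_pathway_definitions(defs)
    return {
        pid: set(grp["kegg_compound_id"].dropna())
        for pid, grp in defs.groupby("pathway_id")
    }


def pathway_names(defs: pd.DataFrame) -> dict[str, str]:
    return dict(defs.drop_duplicates("pathway_id")[["pathway_id", "name"]].values)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check and canonically sort a long-format EHR event table."""
    required = ["person_id", "kind", "code", "date", "systolic", "diastolic"]
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise ValueError(f"EHR table missing columns: {missing}")
    bad_kind = set(events["kind"]) - set(EHR_KINDS)
    if bad_kind:
        raise ValueError(f"invalid event kinds: {sorted(bad_kind)}")
    events = events.copy()
    events["date"] = pd.to_datetime(events["date"])
    is_bp = events["kind"] == "bp_measurement"
    bp_missing = is_bp & (events["systolic"].isna() | events["diastolic"].isna())
    if bp_missing.any():
        rows = events.index[bp_missing].tolist()
        raise ValueError(
            f"bp_measurement rows without systolic/diastolic: rows {rows}"
        )
    nonbp_with_bp = (~is_bp) & (events["systolic"].notna() | events["diastolic"].notna())
    if nonbp_with_bp.any():
        rows = events.index[nonbp_with_bp].tolist()
        raise ValueError(f"non-bp rows carrying blood-pressure values: rows {rows}")
    events = events.sort_values(
        ["person_id", "date", "kind", "code"], kind="mergesort"
    ).reset_index(drop=True)
    return events


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check a covariate table (one row per person)."""
    required = ["person_id", "sex", "bmi", "smoking", "education", "residency",
                "time_of_day", "birth_date", "sample_date", "death_date",
                "followup_end"]
    missing = [c for c in required if c not in cov.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    if cov["person_id"].duplicated().any():
        dups = cov.loc[cov["person_id"].duplicated(), "person_id"].tolist()
        raise ValueError(f"duplicate person ids in covariates: {dups}")
    cov = cov.copy()
    for c in ("birth_date", "sample_date", "death_date", "followup_end"):
        cov[c] = pd.to_datetime(cov[c])
    for name, levels in COVARIATE_LEVELS.items():
        observed = set(cov[name].dropna())
        bad = observed - set(levels)
        if bad:
            raise ValueError(f"unknown {name} levels: {sorted(bad)}")
    if not (cov["birth_date"] < cov["sample_date"]).all():
        raise ValueError("birth_date must precede sample_date for every person")
    if not (cov["sample_date"] <= cov["followup_end"]).all():
        raise ValueError("sample_date must not exceed followup_end")
    has_death = cov["death_date"].notna()
    if not (cov.loc[has_death, "death_date"] >= cov.loc[has_death, "sample_date"]).all():
        raise ValueError("death_date precedes sample_date for some person")
    return cov
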