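"""Readers and writers for the pipeline's tabular text formats.

All tables are plain CSV (TSV for the packaged pathway fixture). Matrix
round-trips are bit-exact: floats are written with shortest-repr precision,
missing cells as the empty string.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .datatypes import (
    MetaboliteMatrix,
    validate_annotation,
    validate_covariates,
    validate_events,
    validate_pathway_definitions,
)

log = logging.getLogger(__name__)

_ID_COL = "person_id"
_DT_COL = "sample_datetime"


def read_matrix(path: str | Path, cfg: RunConfig | None = None) -> MetaboliteMatrix:
    """Read a person x metabolite abundance CSV.

    Layout: one header row (person_id, sample_datetime, metabolite ids...),
    one row per person. Cells matching a missing token (default: empty or
    "NA") parse as missing.
    """
    cfg = cfg or RunConfig()
    path = Path(path)
    header = path.open().readline().rstrip("\n").split(",")
    seen: dict[str, int] = {}
    for h in header:
        seen[h] = seen.get(h, 0) + 1
    dups = sorted(h for h, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate column ids in {path.name}: {dups}")
    na_values = [t for t in cfg.missing_tokens if t != ""]
    df = pd.read_csv(path, dtype={_ID_COL: str}, na_values=na_values,
                     keep_default_na=False)
    if _ID_COL not in df.columns or _DT_COL not in df.columns:
        raise ValueError(f"{path.name} must carry '{_ID_COL}' and '{_DT_COL}' columns")
    df[_DT_COL] = df[_DT_COL].replace("", np.nan)
    values = df.drop(columns=[_ID_COL, _DT_COL])
    values = values.apply(pd.to_numeric)
    values.index = pd.Index(df[_ID_COL], name=_ID_COL)
    sample_dt = pd.Series(pd.to_datetime(df[_DT_COL]).values,
                          index=values.index, name=_DT_COL)
    m = MetaboliteMatrix(values, sample_dt)
    log.info("read matrix %s: %d persons x %d metabolites, %d missing cells",
             path.name, len(m.person_ids), len(m.metabolite_ids), m.n_missing)
    return m


def write_matrix(m: MetaboliteMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.insert(0, _DT_COL, m.sample_datetime.dt.strftime("%Y-%m-%dT%H:%M:%S"))
    out.index.name = _ID_COL
    out.to_csv(path, na_rep="")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, dtype=str, keep_default_na=False)
    ann = ann.replace("", np.nan)
    ann["xenobiotic_origin"] = ann["xenobiotic_origin"].fillna("none")
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, index=False, na_rep="")


def read_pathway_definitions(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    defs = pd.read_csv(path, dtype=str, sep=sep)
    return validate_pathway_definitions(defs)


def write_pathway_definitions(defs: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    defs.to_csv(path, index=False, sep=sep)


def packaged_kegg_fixture() -> Path:
    """Path of the packaged pathway-definition snapshot (TSV).

    A small, user-replaceable snapshot in the format (pathway_id, name,
    kegg_compound_id); regenerate from any pathway database export with the
    same three columns.
    """
    return Path(__file__).parent / "data" / "kegg_fixture.tsv"


def read_ehr(path: str | Path) -> pd.DataFrame:
    """Read a long-format EHR event table, sorted by (person, date)."""
    df = pd.read_csv(path, dtype={"person_id": str, "kind": str, "code": str},
                     keep_default_na=False)
    df["code"] = df["code"].fillna("")
    for c in ("systolic", "diastolic"):
        col = df[c]
        if col.dtype == object:
            col = col.mask(col == "", np.nan)
        df[c] = pd.to_numeric(col)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        parsed = pd.to_datetime(df["date"], errors="coerce")
        bad_rows = df.index[parsed.isna()].tolist()
        raise ValueError(f"unparseable dates in EHR rows {bad_rows}") from exc
    events = validate_events(df)
    log.info("read %d EHR events for %d persons",
             len(events), events["person_id"].nunique())
    return events


def write_ehr(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str}, keep_default_na=False)
    df = df.replace("", np.nan)
    df["bmi"] = pd.to_numeric(df["bmi"])
    return validate_covariates(df)


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    out = cov.copy()
    for c in ("birth_date", "sample_date", "death_date", "followup_end"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def write_run_metadata(path: str | Path, cfg: RunConfig, seed: int | None,
                       stage_counts: dict, outputs: list[str],
                       timestamp: str | None = None) -> None:
    """JSON run-metadata file: config echo, seed, row counts, output list."""
    meta = {
        "config": cfg.to_dict(),
        "seed": seed,
        "stage_counts": stage_counts,
        "outputs": outputs,
    }
    if timestamp is not None:
        meta["timestamp"] = timestamp
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
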