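"""End-to-end orchestration of the discovery and replication workflows.

``run_discovery`` takes the five input tables, executes preprocessing,
pathway reduction, phenotyping, baseline reduction and forward discovery,
writes every artefact as tidy CSV plus a JSON run manifest, and returns the
in-memory results. ``run_replication`` re-runs the discovered pathway on a
second cohort/platform. The manifest records the config echo, input
digests, per-stage row counts, the seed and the output list, so any stage
can be re-run reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .datatypes import MetaboliteMatrix
from .pathways import assemble_dataset, build_pathway_components
from .phenotype import analysis_subset, classify
from .preprocess import complete_case_covariates, run_preprocess
from .survival import (
    build_design,
    build_records,
    descriptive_table,
    forward_discover,
    reduce_baseline,
    replicate,
    single_metabolite_scan,
)

log = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    manifest: dict
    assignments: pd.DataFrame
    scores: pd.DataFrame
    trace: object
    component_set: object
    baseline_terms: list[str]
    records: pd.DataFrame
    scan: pd.DataFrame | None = None


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_final_model(trace, path: Path) -> None:
    fit = trace.final_fit
    df = fit.summary()
    df["aic"] = fit.aic
    df.to_csv(path, index=False)


def run_discovery(
    matrix: MetaboliteMatrix,
    ann: pd.DataFrame,
    defs: pd.DataFrame,
    events: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path,
    seed: int | None = None,
    scan_metabolites: bool = False,
    input_paths: dict[str, str] | None = None,
) -> DiscoveryResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}

    clean, reports = run_preprocess(matrix, cfg.metabolite_missing_max,
                                    cfg.person_missing_max)
    counts["preprocess"] = {
        "metabolites_in": len(matrix.metabolite_ids),
        "metabolites_out": len(clean.metabolite_ids),
        "persons_in": len(matrix.person_ids),
        "persons_out": len(clean.person_ids),
    }

    cov, cov_report = complete_case_covariates(covariates)
    shared = [p for p in clean.values.index if p in set(cov["person_id"])]
    clean = MetaboliteMatrix.unchecked(clean.values.loc[shared],
                                       clean.sample_datetime.loc[shared])
    cov = cov[cov["person_id"].isin(shared)].reset_index(drop=True)
    counts["covariates"] = {"persons_in": len(covariates), "persons_out": len(cov)}

    assignments = classify(events, cov, cfg)
    incident, controls = analysis_subset(assignments)
    counts["phenotype"] = assignments["klass"].value_counts().to_dict()

    cset, mapping = build_pathway_components(clean, ann, defs, cfg)
    scores, loadings = assemble_dataset(cset)
    counts["pathways"] = {
        "groups": len({c.pathway_id for c in cset.components}),
        "components": len(cset.components),
        "retention_drops": len(cset.retention_log),
        "pruned": len(cset.pruning_log),
    }

    desc = descriptive_table(cov, assignments)
    records = build_records(assignments, cov)
    records = records[records["person_id"].isin(scores.index)].reset_index(drop=True)
    counts["survival"] = {"n": len(records),
                          "n_events": int(records["event"].sum())}

    base_fit, base_terms, elimination = reduce_baseline(records, cov, cfg=cfg)
    design, blocks = build_design(cov, base_terms)
    base_design = design[sum((blocks[t] for t in base_terms), [])]
    trace = forward_discover(records, base_design, scores, cfg)
    counts["discovery"] = {"selected": trace.selected,
                           "steps": len(trace.steps)}

    scan = None
    if scan_metabolites:
        mapped = sorted(
            set().union(*mapping.pathway_to_metabolites.values())
            & set(clean.metabolite_ids)
        )
        scan = single_metabolite_scan(records, base_design,
                                      clean.values[mapped], cfg)
        scan.to_csv(out / "single_metabolite_scan.csv", index=False)

    outputs = {
        "phenotypes.csv": assignments.assign(
            first_qualifying_date=assignments["first_qualifying_date"].dt.strftime(
                "%Y-%m-%d")),
        "components.csv": scores.rename_axis("person_id").reset_index(),
        "loadings.csv": loadings,
        "retention_log.csv": pd.DataFrame(cset.retention_log),
        "pruning_log.csv": pd.DataFrame(cset.pruning_log),
        "descriptive_table.csv": desc,
        "records.csv": records,
        "baseline_model.csv": base_fit.summary().assign(aic=base_fit.aic),
        "baseline_elimination.csv": elimination,
        "discovery_trace.csv": pd.concat(trace.steps, ignore_index=True),
        "forest_plot.csv": trace.steps[0].assign(
            hr_low=lambda d: np.exp(d["coef"] - 1.96 * d["se"]),
            hr_high=lambda d: np.exp(d["coef"] + 1.96 * d["se"]),
        ),
    }
    for name, df in outputs.items():
        df.to_csv(out / name, index=False, na_rep="")
    _write_final_model(trace, out / "final_model.csv")
    sched = trace.final_fit.schoenfeld_p or {}
    pd.DataFrame(
        [{"term": t, "p": p} for t, p in sched.items()]
        + [{"term": "GLOBAL", "p": trace.final_fit.global_schoenfeld_p}]
    ).to_csv(out / "schoenfeld.csv", index=False)

    manifest = {
        "config": cfg.to_dict(),
        "seed": seed,
        "input_digests": {k: _digest(v) for k, v in (input_paths or {}).items()},
        "stage_counts": counts,
        "selected_components": trace.selected,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return DiscoveryResult(manifest=manifest, assignments=assignments,
                           scores=scores, trace=trace, component_set=cset,
                           baseline_terms=base_terms, records=records, scan=scan)


def run_replication(
    discovery: DiscoveryResult,
    discovery_ann: pd.DataFrame,
    repl_matrix: MetaboliteMatrix,
    repl_ann: pd.DataFrame,
    repl_events: pd.DataFrame,
    repl_covariates: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Replicate the first discovered pathway component on a second cohort."""
    if not discovery.trace.selected:
        raise ValueError("no discovered pathway component to replicate")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    selected_name = discovery.trace.selected[0]
    comps = [c for c in discovery.component_set.components
             if c.name == selected_name]
    pathway_id = comps[0].pathway_id
    pathway_comps = sorted(
        (c for c in discovery.component_set.components
         if c.pathway_id == pathway_id),
        key=lambda c: c.pc_index,
    )
    fit = discovery.trace.final_fit
    disc_coef = fit.coef[fit.terms.index(selected_name)]

    repl_cov_cc, _ = complete_case_covariates(repl_covariates)
    repl_assign = classify(repl_events, repl_cov_cc, cfg)
    report = replicate(
        pathway_id, pathway_comps, discovery_ann, repl_matrix, repl_ann,
        repl_covariates, repl_assign, cfg, discovery_coef=float(disc_coef),
    )
    report.to_csv(out / "replication_report.csv", index=False)
    log.info("replication of %s: %s", pathway_id,
             report[["pc_index", "hr", "p"]].to_dict("records"))
    return report
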