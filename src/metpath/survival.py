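"""Survival analysis on the age timescale: record building, AIC-driven
baseline reduction, BH-FDR forward discovery of pathway components, the
single-metabolite scan, descriptive statistics, and cross-platform
replication.

Ages are calendar-day differences divided by 365.25. Only incident cases
and controls enter the survival data; entry is the age at sampling, exit
the minimum of diagnosis age, death age and follow-up-end age, and the
event fires only when an incident case exits at diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .cox import CoxFit, bh_adjust, check_proportionality, fit_cox
from .datatypes import COVARIATE_LEVELS, REFERENCE_LEVELS, MetaboliteMatrix
from .pathways import PathwayComponent, pathway_pca
from .preprocess import complete_case_covariates, run_preprocess

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: Full candidate term set of the baseline model.
BASELINE_TERMS = ("sex", "bmi", "smoking", "education", "residency", "time_of_day")


def _age(later: pd.Series, earlier: pd.Series) -> pd.Series:
    return (pd.to_datetime(later) - pd.to_datetime(earlier)).dt.days / DAYS_PER_YEAR


def build_records(assignments: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Left-truncated survival records for incident cases and controls.

    Returns columns (person_id, entry_age, exit_age, event). Records
    violating entry < exit are rejected with the offending ids named.
    """
    keep = assignments[assignments["klass"].isin(["incident_case", "control"])]
    cov = covariates.set_index("person_id")
    rows = []
    for _, row in keep.iterrows():
        pid = row["person_id"]
        c = cov.loc[pid]
        entry = (c["sample_date"] - c["birth_date"]).days / DAYS_PER_YEAR
        censor = (c["followup_end"] - c["birth_date"]).days / DAYS_PER_YEAR
        death = (
            (c["death_date"] - c["birth_date"]).days / DAYS_PER_YEAR
            if pd.notna(c["death_date"]) else np.inf
        )
        if row["klass"] == "incident_case":
            diag = (row["first_qualifying_date"] - c["birth_date"]).days / DAYS_PER_YEAR
            if row["first_qualifying_date"] <= c["sample_date"]:
                raise ValueError(
                    f"incident case {pid!r} diagnosed on or before the sample date "
                    "(classification bug)"
                )
            exit_age = min(diag, death, censor)
            event = int(exit_age == diag)
        else:
            exit_age = min(death, censor)
            event = 0
        rows.append({"person_id": pid, "entry_age": entry,
                     "exit_age": exit_age, "event": event})
    rec = pd.DataFrame(rows)
    bad = rec[~(rec["entry_age"] < rec["exit_age"])]
    if len(bad):
        log.warning("rejecting %d records with entry >= exit: %s",
                    len(bad), bad["person_id"].tolist())
        rec = rec[rec["entry_age"] < rec["exit_age"]]
    return rec.reset_index(drop=True)


def build_design(
    covariates: pd.DataFrame, terms: tuple[str, ...] | list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand covariate terms into a numeric design matrix.

    Categorical terms expand into dummies against the fixed reference
    levels (never/male/rural/low/before10). Returns (design indexed by
    person_id, term -> design-column block map).
    """
    cov = covariates.set_index("person_id")
    cols: dict[str, pd.Series] = {}
    blocks: dict[str, list[str]] = {}
    for term in terms:
        if term in COVARIATE_LEVELS:
            levels = COVARIATE_LEVELS[term]
            ref = REFERENCE_LEVELS[term]
            block = []
            for lv in levels:
                if lv == ref:
                    continue
                name = f"{term}[{lv}]"
                cols[name] = (cov[term] == lv).astype(float)
                block.append(name)
            blocks[term] = block
        else:
            cols[term] = cov[term].astype(float)
            blocks[term] = [term]
    return pd.DataFrame(cols, index=cov.index), blocks


def reduce_baseline(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    full_terms: tuple[str, ...] = BASELINE_TERMS,
    cfg: RunConfig | None = None,
) -> tuple[CoxFit, list[str], pd.DataFrame]:
    """Backward elimination of the baseline model by drop-one AIC.

    At each round every single-term-dropped model is fitted; the
    likelihood-ratio chi-square of each drop is recorded, and the term
    whose removal gives the lowest AIC is eliminated, provided that AIC
    improves on the current model. Categorical terms drop as whole blocks.
    Returns (final fit, final term list, elimination log).
    """
    design, blocks = build_design(covariates, full_terms)
    terms = list(full_terms)
    current = fit_cox(records, design[sum((blocks[t] for t in terms), [])])
    log_rows = []
    while len(terms) > 1:
        candidates = []
        for t in terms:
            reduced_cols = sum((blocks[s] for s in terms if s != t), [])
            red = fit_cox(records, design[reduced_cols])
            lr = 2.0 * (current.log_partial_likelihood - red.log_partial_likelihood)
            df = len(blocks[t])
            candidates.append({
                "dropped_term": t, "aic": red.aic, "lr_chisq": lr, "df": df,
                "lr_p": float(stats.chi2.sf(max(lr, 0.0), df=df)),
                "fit": red,
            })
        best = min(candidates, key=lambda c: c["aic"])
        if best["aic"] >= current.aic:
            break
        log_rows.append({k: v for k, v in best.items() if k != "fit"}
                        | {"aic_before": current.aic})
        terms.remove(best["dropped_term"])
        current = best["fit"]
    elimination = pd.DataFrame(log_rows)
    log.info("baseline reduced to %s (AIC %.2f)", terms, current.aic)
    return current, terms, elimination


@dataclass
class DiscoveryTrace:
    steps: list[pd.DataFrame]           # per-step candidate tables
    selected: list[str]
    final_fit: CoxFit
    baseline_terms: list[str] = field(default_factory=list)


def forward_discover(
    records: pd.DataFrame,
    baseline_design: pd.DataFrame,
    component_table: pd.DataFrame,
    cfg: RunConfig,
) -> DiscoveryTrace:
    """BH-FDR forward selection of pathway components.

    Each step fits one model per remaining candidate (baseline + already
    selected + candidate), collects the candidate Wald p-values, adjusts
    them by Benjamini-Hochberg across the step, and admits the candidate
    with the smallest adjusted p if it is below ``fdr_level`` (ties: smaller
    raw p, then column order). Stops when nothing is admissible. A
    proportionality check is run on the final model.
    """
    zero_var = [c for c in component_table.columns
                if float(component_table[c].std(ddof=0)) == 0.0]
    if zero_var:
        raise ValueError(f"zero-variance component columns: {zero_var}")
    persons = records["person_id"] if "person_id" in records.columns else records.index
    comp = component_table.loc[persons]
    base = baseline_design.loc[persons]

    remaining = list(comp.columns)
    selected: list[str] = []
    steps: list[pd.DataFrame] = []
    while remaining:
        rows = []
        for cand in remaining:
            design = pd.concat([base, comp[selected + [cand]]], axis=1)
            fit = fit_cox(records, design)
            k = fit.terms.index(cand)
            rows.append({"candidate": cand, "coef": fit.coef[k],
                         "hr": fit.hr[k], "se": fit.se[k],
                         "p": fit.wald_p[k], "aic": fit.aic})
        table = pd.DataFrame(rows)
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["step"] = len(steps) + 1
        steps.append(table)
        admissible = table[table["p_adj"] < cfg.fdr_level].copy()
        if len(admissible) == 0:
            break
        admissible["_order"] = admissible["candidate"].map(
            {c: i for i, c in enumerate(remaining)})
        best = admissible.sort_values(["p_adj", "p", "_order"],
                                      kind="mergesort").iloc[0]
        selected.append(best["candidate"])
        remaining.remove(best["candidate"])
    final_design = pd.concat([base, comp[selected]], axis=1)
    final_fit = fit_cox(records, final_design, compute_schoenfeld=True)
    log.info("forward discovery selected %s in %d steps (final AIC %.2f)",
             selected, len(steps), final_fit.aic)
    return DiscoveryTrace(steps=steps, selected=selected, final_fit=final_fit,
                          baseline_terms=list(baseline_design.columns))


def single_metabolite_scan(
    records: pd.DataFrame,
    baseline_design: pd.DataFrame,
    metabolite_table: pd.DataFrame,
    cfg: RunConfig,
) -> pd.DataFrame:
    """One Cox model per metabolite (baseline + metabolite), BH-corrected.

    Returns a table of coef/HR/raw p/adjusted p, one row per metabolite,
    with a proportionality flag computed for BH-significant hits (a hit
    whose model violates proportional hazards is reported but flagged).
    """
    persons = records["person_id"] if "person_id" in records.columns else records.index
    base = baseline_design.loc[persons]
    met = metabolite_table.loc[persons]
    rows = []
    for mid in met.columns:
        design = pd.concat([base, met[[mid]]], axis=1)
        fit = fit_cox(records, design)
        k = fit.terms.index(mid)
        rows.append({"metabolite_id": mid, "coef": fit.coef[k], "hr": fit.hr[k],
                     "p": fit.wald_p[k]})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["ph_violation"] = False
    for i in out.index[out["p_adj"] < cfg.fdr_level]:
        mid = out.loc[i, "metabolite_id"]
        design = pd.concat([base, met[[mid]]], axis=1)
        fit = fit_cox(records, design)
        per_term, global_p = check_proportionality(fit, records, design)
        out.loc[i, "ph_violation"] = bool(global_p < 0.05 or per_term[mid] < 0.05)
    return out


def descriptive_table(
    covariates: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-stratum descriptive statistics with incident-vs-control tests.

    Numeric variables: mean +/- sd per stratum and the Welch two-sample t
    p-value; categorical variables: per-level percentages and the Pearson
    chi-squared p-value (no continuity correction). Strata are prevalent
    cases, incident cases and controls.
    """
    merged = covariates.merge(assignments[["person_id", "klass"]], on="person_id")
    merged["age_at_sample"] = _age(merged["sample_date"], merged["birth_date"])
    end = merged["death_date"].fillna(merged["followup_end"])
    merged["followup_years"] = _age(end, merged["sample_date"])
    strata = {
        "prevalent": merged[merged["klass"] == "prevalent_case"],
        "incident": merged[merged["klass"] == "incident_case"],
        "control": merged[merged["klass"] == "control"],
    }
    if len(strata["incident"]) == 0 or len(strata["control"]) == 0:
        raise ValueError("incident and control strata must be non-empty")

    rows = []
    rows.append({"variable": "N",
                 **{s: float(len(df)) for s, df in strata.items()},
                 "p_incident_vs_control": np.nan})
    for var in ("age_at_sample", "followup_years", "bmi"):
        i = strata["incident"][var].dropna()
        c = strata["control"][var].dropna()
        t = stats.ttest_ind(i, c, equal_var=False)
        rows.append({
            "variable": f"{var} (mean)",
            **{s: float(df[var].mean()) for s, df in strata.items()},
            "p_incident_vs_control": float(t.pvalue),
        })
        rows.append({
            "variable": f"{var} (sd)",
            **{s: float(df[var].std(ddof=1)) for s, df in strata.items()},
            "p_incident_vs_control": np.nan,
        })
    for var, levels in COVARIATE_LEVELS.items():
        i = strata["incident"][var]
        c = strata["control"][var]
        used = [lv for lv in levels if (i == lv).sum() + (c == lv).sum() > 0]
        dropped_levels = set(levels) - set(used)
        if dropped_levels:
            log.warning("%s: levels %s absent in both strata, dropped from test",
                        var, sorted(dropped_levels))
        table = np.array([[(i == lv).sum() for lv in used],
                          [(c == lv).sum() for lv in used]])
        chi2, pval, _, _ = stats.chi2_contingency(table, correction=False)
        for j, lv in enumerate(used):
            rows.append({
                "variable": f"{var}={lv} (%)",
                **{s: float(100.0 * (df[var] == lv).mean()) for s, df in strata.items()},
                "p_incident_vs_control": float(pval) if j == 0 else np.nan,
            })
    return pd.DataFrame(rows)


def replicate(
    pathway_id: str,
    discovery_components: list[PathwayComponent],
    discovery_ann: pd.DataFrame,
    repl_matrix: MetaboliteMatrix,
    repl_ann: pd.DataFrame,
    repl_covariates: pd.DataFrame,
    repl_assignments: pd.DataFrame,
    cfg: RunConfig,
    discovery_coef: float | None = None,
) -> pd.DataFrame:
    """Cross-platform replication of a discovered pathway.

    The replication matrix is restricted to the metabolites whose KEGG
    compound ids overlap the discovery pathway's loadings, preprocessed and
    re-decomposed by PCA; the baseline is re-reduced on the replication
    covariates; and each recomputed PC is tested alongside the baseline.
    The report carries per-PC HR and p, the cosine similarity between the
    recomputed and discovery loading vectors on the overlap (after sign
    alignment), and the direction concordance with the discovery
    coefficient.
    """
    disc_compounds = (
        discovery_ann.set_index("metabolite_id")["kegg_compound_id"]
        .reindex(discovery_components[0].loadings.index)
    )
    repl_by_compound = (
        repl_ann.dropna(subset=["kegg_compound_id"])
        .set_index("kegg_compound_id")["metabolite_id"]
    )
    overlap_compounds = [c for c in disc_compounds.dropna()
                         if c in repl_by_compound.index
                         and repl_by_compound[c] in repl_matrix.metabolite_ids]
    if len(overlap_compounds) < 2:
        raise ValueError(
            f"fewer than 2 overlapping metabolites for pathway {pathway_id}"
        )
    overlap_repl = [repl_by_compound[c] for c in overlap_compounds]

    clean, _ = run_preprocess(repl_matrix, cfg.metabolite_missing_max,
                              cfg.person_missing_max)
    comps = pathway_pca(clean, set(overlap_repl), cfg, pathway_id=pathway_id)

    cov, _ = complete_case_covariates(repl_covariates)
    records = build_records(repl_assignments, cov)
    records = records[records["person_id"].isin(clean.values.index)]
    cov = cov[cov["person_id"].isin(records["person_id"])]
    base_fit, base_terms, _ = reduce_baseline(records, cov, cfg=cfg)
    base_design, blocks = build_design(cov, base_terms)
    base_cols = sum((blocks[t] for t in base_terms), [])
    base_design = base_design[base_cols]

    # align discovery loadings to compound-id space for the cosine diagnostic
    disc_load_by_compound = {}
    for comp in discovery_components:
        s = pd.Series(comp.loadings.values,
                      index=disc_compounds.reindex(comp.loadings.index).values)
        disc_load_by_compound[comp.pc_index] = s

    rows = []
    for comp in comps:
        scores = comp.scores.rename(comp.name).to_frame()
        design = pd.concat(
            [base_design, scores.loc[base_design.index]], axis=1)
        fit = fit_cox(records, design)
        k = fit.terms.index(comp.name)
        repl_load = pd.Series(
            comp.loadings.values,
            index=[overlap_compounds[overlap_repl.index(m)] for m in comp.loadings.index],
        )
        cosines = {}
        for pc_idx, disc_load in disc_load_by_compound.items():
            common = [c for c in repl_load.index if c in disc_load.index]
            a = repl_load[common].to_numpy()
            b = disc_load[common].to_numpy()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            cosines[pc_idx] = float(abs(a @ b) / denom) if denom > 0 else np.nan
        best_match = max(cosines, key=lambda i: cosines[i])
        # sign-align the replication coefficient to the matched discovery PC
        common = [c for c in repl_load.index
                  if c in disc_load_by_compound[best_match].index]
        dot = float(repl_load[common] @ disc_load_by_compound[best_match][common])
        aligned_coef = fit.coef[k] * np.sign(dot if dot != 0 else 1.0)
        concordant = (
            np.nan if discovery_coef is None
            else float(np.sign(aligned_coef) == np.sign(discovery_coef))
        )
        rows.append({
            "pathway_id": pathway_id,
            "pc_index": comp.pc_index,
            "n_overlap": len(overlap_repl),
            "coef": fit.coef[k],
            "hr": fit.hr[k],
            "p": fit.wald_p[k],
            "matched_discovery_pc": best_match,
            "cosine_similarity": cosines[best_match],
            "direction_concordance": concordant,
        })
    return pd.DataFrame(rows)
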