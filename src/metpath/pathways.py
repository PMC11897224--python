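"""KEGG-pathway principal-component reduction of the metabolite matrix.

Metabolites with known KEGG compound ids are mapped into pathways; pathways
with at least ``pathway_min_size`` matched metabolites (default 10) are
reduced by PCA to at most ``pc_cap`` components (default 3). Chemical
xenobiotics, which map to no human pathway, are pooled into one extra PCA
group. A trailing component is dropped when it adds less than
``variance_gain_min`` percentage points of explained variance, and
cross-pathway component pairs correlated above ``corr_prune`` in absolute
value lose the component from the smaller pathway.

PCA runs on the correlation matrix by default (z-scored metabolites):
log-abundances have heterogeneous variances across assays, and scaling makes
component scores comparable between pathways. Set ``pca_scale: covariance``
to skip the scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .datatypes import MetaboliteMatrix, pathway_compound_sets

log = logging.getLogger(__name__)

XENOBIOTIC_SET = "xenobiotic_set"


@dataclass
class PathwayMapping:
    pathway_to_metabolites: dict[str, set[str]]
    xenobiotic_set: set[str]
    excluded_pathways: list[tuple[str, str]]  # (pathway_id, reason)


@dataclass
class PathwayComponent:
    pathway_id: str
    pc_index: int                      # 1-based
    loadings: pd.Series                # metabolite_id -> loading, unit norm
    variance_fraction: float
    scores: pd.Series                  # person_id -> score, mean 0

    @property
    def name(self) -> str:
        return f"{self.pathway_id}_PC{self.pc_index}"


@dataclass
class PathwayComponentSet:
    components: list[PathwayComponent]
    pruning_log: list[dict] = field(default_factory=list)
    retention_log: list[dict] = field(default_factory=list)
    pathway_sizes: dict[str, int] = field(default_factory=dict)


def map_to_pathways(
    ann: pd.DataFrame,
    defs: pd.DataFrame,
    matrix_ids: set[str],
    cfg: RunConfig,
) -> PathwayMapping:
    """Map matrix metabolites into pathways via their KEGG compound ids.

    Pathways on the configured exclusion list are dropped with a recorded
    reason. The xenobiotic set collects metabolites annotated with
    superpathway "xenobiotics" and chemical (non-microbial) origin.
    """
    compounds = pathway_compound_sets(defs)
    ann = ann[ann["metabolite_id"].isin(matrix_ids)]
    by_compound: dict[str, set[str]] = {}
    for mid, cid in ann[["metabolite_id", "kegg_compound_id"]].dropna().values:
        by_compound.setdefault(cid, set()).add(mid)

    excluded = [(pid, "superpathway") for pid in cfg.excluded_pathways if pid in compounds]
    mapping: dict[str, set[str]] = {}
    for pid, cset in compounds.items():
        if pid in cfg.excluded_pathways:
            continue
        members: set[str] = set()
        for cid in cset:
            members |= by_compound.get(cid, set())
        mapping[pid] = members

    xeno = set(
        ann.loc[
            (ann["superpathway"] == "xenobiotics")
            & (ann["xenobiotic_origin"] == "chemical"),
            "metabolite_id",
        ]
    )
    if not any(mapping.values()) and not xeno:
        log.warning("no metabolite mapped to any pathway")
    return PathwayMapping(mapping, xeno, excluded)


def select_pathways(mapping: PathwayMapping, min_size: int) -> list[str]:
    """Pathways with >= ``min_size`` matched metabolites, largest first;
    the xenobiotic set is always appended as an extra group."""
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    qualifying = [
        pid for pid, members in mapping.pathway_to_metabolites.items()
        if len(members) >= min_size
    ]
    if not qualifying and not mapping.xenobiotic_set:
        raise ValueError(f"no pathway has >= {min_size} matched metabolites")
    qualifying.sort(key=lambda pid: (-len(mapping.pathway_to_metabolites[pid]), pid))
    if mapping.xenobiotic_set:
        qualifying.append(XENOBIOTIC_SET)
    return qualifying


def pathway_pca(
    m: MetaboliteMatrix,
    members: set[str],
    cfg: RunConfig,
    pathway_id: str = "",
) -> list[PathwayComponent]:
    """Leading principal components of one pathway's member metabolites.

    Members are z-scored (correlation PCA) unless ``pca_scale`` is
    "covariance". Component sign is fixed so the largest-|loading|
    metabolite loads positively (ties broken by lexicographically smallest
    metabolite id). Returns at most ``pc_cap`` components.
    """
    cols = sorted(members & set(m.metabolite_ids))
    if len(cols) < 2:
        raise ValueError(f"pathway {pathway_id or '?'}: needs >= 2 member metabolites")
    X = m.values[cols].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("pathway PCA requires an imputed (complete) matrix")
    sd = X.std(axis=0, ddof=1)
    zero = np.array(cols)[sd == 0]
    if zero.size:
        raise ValueError(f"zero-variance metabolites: {list(zero)}")
    Xc = X - X.mean(axis=0)
    if cfg.pca_scale == "correlation":
        Xc = Xc / sd
    n, p = Xc.shape
    # SVD route; eigenvalues of the empirical correlation/covariance matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    k = min(cfg.pc_cap, p)
    comps: list[PathwayComponent] = []
    for j in range(k):
        load = Vt[j]
        # deterministic sign: largest-|loading| metabolite positive
        mx = np.max(np.abs(load))
        anchor = min(i for i in range(p) if np.isclose(abs(load[i]), mx, rtol=0, atol=1e-12))
        if load[anchor] < 0:
            load = -load
        scores = Xc @ load
        comps.append(PathwayComponent(
            pathway_id=pathway_id,
            pc_index=j + 1,
            loadings=pd.Series(load, index=cols),
            variance_fraction=float(eigvals[j] / total),
            scores=pd.Series(scores, index=m.values.index),
        ))
    return comps


def retain_components(
    components: list[PathwayComponent], gain_min: float
) -> tuple[list[PathwayComponent], list[dict]]:
    """Apply the cumulative-variance-gain retention rule within one pathway.

    PC1 is always kept. PC(k+1) is dropped when its variance fraction (the
    cumulative gain over PCk) is below ``gain_min`` percentage points; the
    drop is hierarchical, so losing PC2 also loses PC3.
    """
    kept: list[PathwayComponent] = []
    dropped_log: list[dict] = []
    dropping = False
    for i, comp in enumerate(components):
        if i == 0:
            kept.append(comp)
            continue
        gain_pct = comp.variance_fraction * 100.0
        if dropping or gain_pct < gain_min:
            dropping = True
            dropped_log.append({
                "pathway_id": comp.pathway_id,
                "pc_index": comp.pc_index,
                "variance_gain_pct": gain_pct,
            })
        else:
            kept.append(comp)
    return kept, dropped_log


def prune_correlated(
    all_components: list[PathwayComponent],
    pathway_sizes: dict[str, int],
    threshold: float,
    prune_unit: str = "component",
) -> PathwayComponentSet:
    """Remove cross-pathway components correlated above ``threshold``.

    Pairs are processed in descending |Pearson r| (deterministic tie-break
    on names); for each still-intact pair with |r| strictly above the
    threshold, the component from the pathway with fewer matched metabolites
    is removed (size tie: the lexicographically larger pathway id loses).
    With ``prune_unit="pathway"``, every component of the losing pathway is
    removed. Within-pathway pairs are orthogonal by construction and never
    tested.
    """
    comps = list(all_components)
    n = len(comps)
    if n == 0:
        return PathwayComponentSet([], pathway_sizes=dict(pathway_sizes))
    persons = comps[0].scores.index
    for c in comps:
        if not c.scores.index.equals(persons):
            raise ValueError("component scores not aligned on an identical person set")
    S = np.column_stack([c.scores.to_numpy() for c in comps])
    R = np.corrcoef(S, rowvar=False)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if comps[i].pathway_id == comps[j].pathway_id:
                continue
            pairs.append((abs(float(R[i, j])), comps[i].name, comps[j].name, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    alive = [True] * n
    pruning_log: list[dict] = []
    for r, _, _, i, j in pairs:
        if r <= threshold:
            break
        if not (alive[i] and alive[j]):
            continue
        a, b = comps[i], comps[j]
        sa = pathway_sizes.get(a.pathway_id, 0)
        sb = pathway_sizes.get(b.pathway_id, 0)
        if sa < sb:
            li, keeper = i, b
        elif sb < sa:
            li, keeper = j, a
        else:
            li, keeper = (i, b) if a.pathway_id > b.pathway_id else (j, a)
        loser = comps[li]
        victims = (
            [k for k in range(n) if alive[k] and comps[k].pathway_id == loser.pathway_id]
            if prune_unit == "pathway"
            else [li]
        )
        for k in victims:
            alive[k] = False
            pruning_log.append({
                "removed": comps[k].name,
                "partner": keeper.name,
                "correlation": r,
                "rule": f"|r|>{threshold} ({prune_unit}-level, smaller pathway loses)",
            })
    kept = [c for c, a in zip(comps, alive) if a]
    return PathwayComponentSet(kept, pruning_log=pruning_log,
                               pathway_sizes=dict(pathway_sizes))


def assemble_dataset(
    cset: PathwayComponentSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Person x component score table plus a loadings/variance metadata table.

    Columns are named ``<pathway_id>_PC<k>``.
    """
    if not cset.components:
        raise ValueError("empty component set")
    persons = cset.components[0].scores.index
    for c in cset.components:
        if not c.scores.index.equals(persons):
            raise ValueError("person-set mismatch across components")
    scores = pd.DataFrame({c.name: c.scores for c in cset.components})
    meta_rows = []
    for c in cset.components:
        for mid, loading in c.loadings.items():
            meta_rows.append({
                "component": c.name,
                "pathway_id": c.pathway_id,
                "pc_index": c.pc_index,
                "variance_fraction": c.variance_fraction,
                "metabolite_id": mid,
                "loading": loading,
            })
    return scores, pd.DataFrame(meta_rows)


def build_pathway_components(
    m: MetaboliteMatrix,
    ann: pd.DataFrame,
    defs: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[PathwayComponentSet, PathwayMapping]:
    """Full reduction: map -> select -> per-pathway PCA -> retain -> prune."""
    mapping = map_to_pathways(ann, defs, set(m.metabolite_ids), cfg)
    selected = select_pathways(mapping, cfg.pathway_min_size)
    sizes: dict[str, int] = {}
    retained: list[PathwayComponent] = []
    retention_log: list[dict] = []
    for pid in selected:
        members = (mapping.xenobiotic_set if pid == XENOBIOTIC_SET
                   else mapping.pathway_to_metabolites[pid])
        sizes[pid] = len(members & set(m.metabolite_ids))
        comps = pathway_pca(m, members, cfg, pathway_id=pid)
        kept, dropped = retain_components(comps, cfg.variance_gain_min)
        retained.extend(kept)
        retention_log.extend(dropped)
    cset = prune_correlated(retained, sizes, cfg.corr_prune, cfg.prune_unit)
    cset.retention_log = retention_log
    log.info("pathway components: %d groups -> %d components (%d retention drops, "
             "%d pruned)", len(selected), len(cset.components),
             len(retention_log), len(cset.pruning_log))
    return cset, mapping
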