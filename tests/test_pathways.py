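"""Pathway mapping, per-pathway PCA, retention and pruning rules."""

import numpy as np
import pandas as pd
import pytest

from metpath.config import RunConfig
from metpath.datatypes import MetaboliteMatrix
from metpath.pathways import (
    PathwayComponent,
    XENOBIOTIC_SET,
    assemble_dataset,
    build_pathway_components,
    map_to_pathways,
    pathway_pca,
    prune_correlated,
    retain_components,
    select_pathways,
)

from oracles import pca_eigh


def matrix_from(arr, mets):
    df = pd.DataFrame(np.asarray(arr, float),
                      index=pd.Index([f"p{i}" for i in range(len(arr))],
                                     name="person_id"),
                      columns=mets)
    dts = pd.Series(pd.to_datetime(["2005-01-01"] * len(df)), index=df.index)
    return MetaboliteMatrix.unchecked(df, dts)


@pytest.fixture
def mapping_inputs():
    ann = pd.DataFrame({
        "metabolite_id": ["m1", "m2", "m3", "x1", "x2", "u1"],
        "name": list("abcdef"),
        "kegg_compound_id": ["C00041", "C00022", "C00099", np.nan, np.nan, np.nan],
        "superpathway": ["metabolism"] * 3 + ["xenobiotics"] * 2 + ["unannotated"],
        "xenobiotic_origin": ["none"] * 3 + ["chemical", "microbial", "none"],
    })
    defs = pd.DataFrame({
        "pathway_id": ["hsa01200", "hsa01200", "hsa01100", "hsa01100", "hsa00250"],
        "name": ["Carbon metabolism"] * 2 + ["Metabolic pathways"] * 2
                + ["Ala/Asp/Glu metabolism"],
        "kegg_compound_id": ["C00041", "C00022", "C00041", "C00022", "C00041"],
    })
    return ann, defs


class TestMapping:
    def test_compound_maps_into_pathway(self, mapping_inputs, cfg):
        ann, defs = mapping_inputs
        mapping = map_to_pathways(ann, defs, {"m1", "m2", "m3", "x1", "x2", "u1"}, cfg)
        assert mapping.pathway_to_metabolites["hsa01200"] == {"m1", "m2"}

    def test_superpathway_exclusion_recorded(self, mapping_inputs, cfg):
        ann, defs = mapping_inputs
        mapping = map_to_pathways(ann, defs, {"m1", "m2"}, cfg)
        assert "hsa01100" not in mapping.pathway_to_metabolites
        assert ("hsa01100", "superpathway") in mapping.excluded_pathways

    def test_microbial_xenobiotics_not_pooled(self, mapping_inputs, cfg):
        ann, defs = mapping_inputs
        mapping = map_to_pathways(ann, defs, {"m1", "x1", "x2"}, cfg)
        assert mapping.xenobiotic_set == {"x1"}

    def test_absent_from_matrix_not_mapped(self, mapping_inputs, cfg):
        ann, defs = mapping_inputs
        mapping = map_to_pathways(ann, defs, {"m1"}, cfg)
        assert mapping.pathway_to_metabolites["hsa01200"] == {"m1"}


class TestSelect:
    def make_mapping(self, sizes, xeno=0):
        from metpath.pathways import PathwayMapping
        return PathwayMapping(
            {pid: {f"{pid}_m{i}" for i in range(k)} for pid, k in sizes.items()},
            {f"x{i}" for i in range(xeno)}, [],
        )

    def test_at_least_min_size_inclusive(self):
        mapping = self.make_mapping({"hsa1": 10, "hsa2": 9})
        assert select_pathways(mapping, 10) == ["hsa1"]

    def test_sorted_by_descending_size(self):
        mapping = self.make_mapping({"hsaA": 12, "hsaB": 15})
        assert select_pathways(mapping, 10) == ["hsaB", "hsaA"]

    def test_xenobiotic_set_always_appended(self):
        mapping = self.make_mapping({"hsa1": 10}, xeno=3)
        assert select_pathways(mapping, 10) == ["hsa1", XENOBIOTIC_SET]

    def test_nothing_qualifying_raises(self):
        mapping = self.make_mapping({"hsa1": 4})
        with pytest.raises(ValueError):
            select_pathways(mapping, 10)


class TestPathwayPCA:
    def test_two_perfectly_correlated_metabolites(self, cfg):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200)
        m = matrix_from(np.column_stack([a, 2 * a + 1]), ["A", "B"])
        comps = pathway_pca(m, {"A", "B"}, cfg, "hsaX")
        assert comps[0].variance_fraction == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.abs(comps[0].loadings), np.sqrt(0.5), atol=1e-12)
        assert comps[0].loadings.iloc[0] > 0

    def test_matches_eigendecomposition_oracle(self, cfg):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n, p = 80, int(rng.integers(3, 8))
            X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
            mets = [f"M{j}" for j in range(p)]
            m = matrix_from(X, mets)
            comps = pathway_pca(m, set(mets), cfg, "hsaX")
            fracs, vecs = pca_eigh(X)
            for k, comp in enumerate(comps):
                assert comp.variance_fraction == pytest.approx(fracs[k], abs=1e-8)
                v = vecs[:, k]
                got = comp.loadings.reindex(mets).to_numpy()
                assert min(np.abs(got - v).max(), np.abs(got + v).max()) < 1e-8

    def test_scores_centred_and_orthogonal(self, cfg):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((120, 5))
        mets = [f"M{j}" for j in range(5)]
        comps = pathway_pca(matrix_from(X, mets), set(mets), cfg, "hsaX")
        for c in comps:
            assert abs(c.scores.mean()) < 1e-10
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                r = np.corrcoef(comps[i].scores, comps[j].scores)[0, 1]
                assert abs(r) < 1e-10

    def test_sign_convention_flip_invariance(self, cfg):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 4)) @ rng.standard_normal((4, 4))
        mets = [f"M{j}" for j in range(4)]
        base = pathway_pca(matrix_from(X, mets), set(mets), cfg, "hsaX")
        X2 = X.copy()
        X2[:, 2] *= -1
        flipped = pathway_pca(matrix_from(X2, mets), set(mets), cfg, "hsaX")
        for b, f in zip(base, flipped):
            assert f.variance_fraction == pytest.approx(b.variance_fraction,
                                                        abs=1e-10)
            # documented sign rule: largest-|loading| metabolite positive
            anchor = f.loadings.abs().idxmax()
            assert f.loadings[anchor] > 0

    def test_zero_variance_metabolite_named(self, cfg):
        X = np.column_stack([np.ones(50), np.random.default_rng(0).normal(size=50)])
        with pytest.raises(ValueError, match="M0"):
            pathway_pca(matrix_from(X, ["M0", "M1"]), {"M0", "M1"}, cfg, "hsaX")


def comp(pathway, k, frac, scores=None, loadings=None):
    n = 10 if scores is None else len(scores)
    return PathwayComponent(
        pathway_id=pathway, pc_index=k,
        loadings=pd.Series(loadings if loadings is not None else [1.0],
                           index=["m"]),
        variance_fraction=frac,
        scores=pd.Series(scores if scores is not None else np.zeros(n),
                         index=[f"p{i}" for i in range(n)]),
    )


class TestRetention:
    @pytest.mark.parametrize("fracs,kept", [
        ((0.50, 0.10, 0.03), [1, 2]),       # PC3 gain 3% < 5%
        ((0.50, 0.04, 0.10), [1]),          # hierarchical: losing PC2 loses PC3
        ((0.40, 0.30, 0.20), [1, 2, 3]),
        ((0.60, 0.05, 0.04), [1, 2]),       # gain exactly 5%: kept (strict <)
        ((0.90, 0.049, 0.03), [1]),
    ])
    def test_variance_gain_rule(self, fracs, kept):
        comps = [comp("hsaX", k + 1, f) for k, f in enumerate(fracs)]
        out, logged = retain_components(comps, 5.0)
        assert [c.pc_index for c in out] == kept
        assert len(logged) == len(fracs) - len(kept)


def corr_scores(n=64, r=0.95, seed=0):
    """Two score vectors with exactly-controlled correlation (u vs a*u+b*w)."""
    rng = np.random.default_rng(seed)
    u = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
    w = np.tile([1.0, -1.0, 1.0, -1.0], n // 4)
    return u, r * u + np.sqrt(1 - r**2) * w


class TestPruning:
    def pair(self, r, size_a=20, size_b=12, pa="hsaA", pb="hsaB"):
        u, v = corr_scores(r=r)
        A = comp(pa, 1, 0.5, scores=u)
        B = comp(pb, 1, 0.5, scores=v)
        return [A, B], {pa: size_a, pb: size_b}

    def test_smaller_pathway_component_removed(self):
        comps, sizes = self.pair(0.95)
        out = prune_correlated(comps, sizes, 0.9)
        assert [c.pathway_id for c in out.components] == ["hsaA"]
        entry = out.pruning_log[0]
        assert entry["removed"] == "hsaB_PC1"
        assert entry["partner"] == "hsaA_PC1"
        assert entry["correlation"] == pytest.approx(0.95, abs=1e-9)

    def test_boundary_exactly_at_threshold_keeps_both(self):
        # 3-4-5 construction: empirical r is exactly 0.8 in floating point
        u = np.tile([1.0, 1.0, -1.0, -1.0], 16)
        w = np.tile([1.0, -1.0, 1.0, -1.0], 16)
        v = 4 * u + 3 * w
        r = np.corrcoef(u, v)[0, 1]
        assert abs(r - 0.8) < 1e-15 and r <= 0.8
        comps = [comp("hsaA", 1, 0.5, scores=u), comp("hsaB", 1, 0.5, scores=v)]
        out = prune_correlated(comps, {"hsaA": 20, "hsaB": 12}, 0.8)
        assert len(out.components) == 2
        assert out.pruning_log == []

    def test_just_above_and_below_default_threshold(self):
        comps, sizes = self.pair(0.905)
        assert len(prune_correlated(comps, sizes, 0.9).components) == 1
        comps, sizes = self.pair(0.889)
        assert len(prune_correlated(comps, sizes, 0.9).components) == 2

    def test_negative_correlation_pruned_by_absolute_value(self):
        comps, sizes = self.pair(-0.95)
        out = prune_correlated(comps, sizes, 0.9)
        assert len(out.components) == 1
        assert out.pruning_log[0]["correlation"] == pytest.approx(0.95, abs=1e-9)

    def test_size_tie_breaks_to_larger_pathway_id(self):
        comps, sizes = self.pair(0.95, size_a=12, size_b=12)
        out = prune_correlated(comps, sizes, 0.9)
        assert [c.pathway_id for c in out.components] == ["hsaA"]

    def test_within_pathway_pairs_never_tested(self):
        u, v = corr_scores(r=0.99)
        comps = [comp("hsaA", 1, 0.5, scores=u), comp("hsaA", 2, 0.3, scores=v)]
        out = prune_correlated(comps, {"hsaA": 10}, 0.9)
        assert len(out.components) == 2

    def test_pathway_level_pruning_drops_all_components(self):
        u, v = corr_scores(r=0.95)
        comps = [comp("hsaA", 1, 0.5, scores=u),
                 comp("hsaB", 1, 0.5, scores=v),
                 comp("hsaB", 2, 0.3, scores=np.ones(64))]
        out = prune_correlated(comps, {"hsaA": 20, "hsaB": 12}, 0.9,
                               prune_unit="pathway")
        assert [c.pathway_id for c in out.components] == ["hsaA"]

    def test_retained_cross_pathway_correlations_below_threshold(self):
        rng = np.random.default_rng(8)
        comps = []
        for i in range(6):
            comps.append(comp(f"hsa{i}", 1, 0.5,
                              scores=rng.standard_normal(64)))
        # plant one highly correlated pair
        comps[1].scores = comps[0].scores * 0.96 + 0.05 * rng.standard_normal(64)
        out = prune_correlated(comps, {f"hsa{i}": 10 + i for i in range(6)}, 0.9)
        S = np.column_stack([c.scores for c in out.components])
        R = np.abs(np.corrcoef(S, rowvar=False))
        np.fill_diagonal(R, 0)
        assert R.max() <= 0.9


class TestAssemble:
    def test_column_count_bookkeeping(self):
        comps = [comp(f"hsa{i}", k, 0.5 / k, scores=np.arange(10.0))
                 for i in range(3) for k in (1, 2, 3)]
        from metpath.pathways import PathwayComponentSet
        scores, meta = assemble_dataset(PathwayComponentSet(comps))
        assert scores.shape == (10, 9)
        assert list(scores.columns)[:3] == ["hsa0_PC1", "hsa0_PC2", "hsa0_PC3"]

    def test_person_mismatch_rejected(self):
        a = comp("hsaA", 1, 0.5, scores=np.arange(10.0))
        b = comp("hsaB", 1, 0.5, scores=np.arange(8.0))
        from metpath.pathways import PathwayComponentSet
        with pytest.raises(ValueError, match="person-set"):
            assemble_dataset(PathwayComponentSet([a, b]))


def test_single_factor_pathway_pc1_recovers_generating_loadings(cfg,
                                                                small_study):
    """On simulated single-factor pathways PC1 tracks the latent factor."""
    matrix, ann, defs, _, _, truth = small_study
    from metpath.preprocess import run_preprocess
    clean, _ = run_preprocess(matrix)
    cset, mapping = build_pathway_components(clean, ann, defs, cfg)
    for j in range(truth.design.n_pathways):
        name = f"hsa9{j:04d}_PC1"
        pc1 = [c for c in cset.components if c.name == name]
        if not pc1:
            continue
        r = np.corrcoef(pc1[0].scores,
                        truth.factors.iloc[:, j].loc[pc1[0].scores.index])[0, 1]
        assert abs(r) > 0.9
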