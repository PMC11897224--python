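"""Record building, baseline reduction, forward discovery, descriptives,
single-metabolite scan and replication."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metpath.config import RunConfig
from metpath.experiments import prepare_cohort
from metpath.pipeline import run_discovery, run_replication
from metpath.survival import (
    build_design,
    build_records,
    descriptive_table,
    forward_discover,
    reduce_baseline,
    single_metabolite_scan,
)
from metpath.synth import SimulationDesign, simulate_study


def cov_row(pid, birth, sample, death=None, end="2021-12-31", **kw):
    row = {"person_id": pid, "sex": "male", "bmi": 25.0, "smoking": "never",
           "education": "low", "residency": "rural", "time_of_day": "before10",
           "birth_date": pd.Timestamp(birth), "sample_date": pd.Timestamp(sample),
           "death_date": pd.Timestamp(death) if death else pd.NaT,
           "followup_end": pd.Timestamp(end)}
    row.update(kw)
    return row


def assign_row(pid, klass, date=None):
    return {"person_id": pid, "klass": klass,
            "first_qualifying_date": pd.Timestamp(date) if date else pd.NaT,
            "rule_fired": ""}


class TestBuildRecords:
    def test_incident_age_arithmetic(self):
        cov = pd.DataFrame([cov_row("p1", "1960-01-01", "2005-01-01")])
        assign = pd.DataFrame([assign_row("p1", "incident_case", "2010-01-01")])
        rec = build_records(assign, cov).iloc[0]
        assert rec["entry_age"] == pytest.approx(45.0, abs=0.01)
        assert rec["exit_age"] == pytest.approx(50.0, abs=0.01)
        assert rec["event"] == 1

    def test_control_death_precedes_followup_end(self):
        cov = pd.DataFrame([cov_row("p1", "1960-01-01", "2005-01-01",
                                    death="2012-01-01")])
        assign = pd.DataFrame([assign_row("p1", "control")])
        rec = build_records(assign, cov).iloc[0]
        assert rec["exit_age"] == pytest.approx(52.0, abs=0.01)
        assert rec["event"] == 0

    def test_control_alive_censored_at_followup_end(self):
        cov = pd.DataFrame([cov_row("p1", "1960-01-01", "2005-01-01")])
        assign = pd.DataFrame([assign_row("p1", "control")])
        rec = build_records(assign, cov).iloc[0]
        assert rec["exit_age"] == pytest.approx(61.99, abs=0.02)

    def test_incident_diagnosed_before_sample_is_a_bug(self):
        cov = pd.DataFrame([cov_row("p1", "1960-01-01", "2005-01-01")])
        assign = pd.DataFrame([assign_row("p1", "incident_case", "2004-01-01")])
        with pytest.raises(ValueError, match="classification bug"):
            build_records(assign, cov)

    def test_only_incident_and_controls_enter(self):
        cov = pd.DataFrame([cov_row(f"p{i}", "1960-01-01", "2005-01-01")
                            for i in range(4)])
        assign = pd.DataFrame([
            assign_row("p0", "incident_case", "2010-01-01"),
            assign_row("p1", "control"),
            assign_row("p2", "prevalent_case", "2000-01-01"),
            assign_row("p3", "uncertain"),
        ])
        rec = build_records(assign, cov)
        assert set(rec["person_id"]) == {"p0", "p1"}


def _survival_cohort(rng, n=400, beta_x=0.5):
    """Cohort where only covariate x drives the hazard."""
    x = rng.standard_normal(n)
    noise1 = rng.standard_normal(n)
    entry = rng.uniform(40, 60, n)
    t = entry + rng.exponential(1 / (0.03 * np.exp(beta_x * x)))
    cens = entry + rng.uniform(2, 20, n)
    exit_ = np.minimum(t, cens)
    event = (t <= cens).astype(int)
    rec = pd.DataFrame({"person_id": [f"p{i}" for i in range(n)],
                        "entry_age": entry, "exit_age": exit_, "event": event})
    design = pd.DataFrame({"x": x, "noise1": noise1,
                           "noise2": rng.standard_normal(n)},
                          index=rec["person_id"])
    return rec, design


class TestReduceBaseline:
    def _covariates(self, rng, n):
        return pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "bmi": rng.normal(26, 4, n),
            "smoking": rng.choice(["never", "former", "current"], n),
            "education": rng.choice(["low", "intermediate", "high"], n),
            "residency": rng.choice(["rural", "town", "city", "unknown"], n),
            "time_of_day": rng.choice(["before10", "h10to15", "after15"], n),
            "birth_date": pd.Timestamp("1950-01-01"),
            "sample_date": pd.Timestamp("2005-01-01"),
            "death_date": pd.NaT,
            "followup_end": pd.Timestamp("2021-12-31"),
        })

    def test_keeps_true_effect_drops_noise(self, cfg):
        rng = np.random.default_rng(41)
        n = 500
        cov = self._covariates(rng, n)
        # hazard driven by BMI only; all other covariates are noise
        entry = 55.0 + rng.uniform(0, 5, n)
        t = entry + rng.exponential(
            1 / (0.02 * np.exp(0.10 * (cov["bmi"].to_numpy() - 26))))
        cens = entry + rng.uniform(2, 25, n)
        rec = pd.DataFrame({"person_id": cov["person_id"],
                            "entry_age": entry,
                            "exit_age": np.minimum(t, cens),
                            "event": (t <= cens).astype(int)})
        fit, terms, log = reduce_baseline(rec, cov, cfg=cfg)
        assert "bmi" in terms

    def test_single_term_model_is_identity(self, cfg):
        rng = np.random.default_rng(42)
        cov = self._covariates(rng, 120)
        entry = 50 + rng.uniform(0, 5, 120)
        rec = pd.DataFrame({"person_id": cov["person_id"], "entry_age": entry,
                            "exit_age": entry + rng.uniform(1, 10, 120),
                            "event": rng.integers(0, 2, 120)})
        fit, terms, log = reduce_baseline(rec, cov, full_terms=("bmi",), cfg=cfg)
        assert terms == ["bmi"]
        assert len(log) == 0

    def test_elimination_log_monotone_in_aic(self, cfg):
        rng = np.random.default_rng(43)
        cov = self._covariates(rng, 300)
        entry = 50 + rng.uniform(0, 5, 300)
        rec = pd.DataFrame({"person_id": cov["person_id"], "entry_age": entry,
                            "exit_age": entry + rng.uniform(1, 10, 300),
                            "event": rng.integers(0, 2, 300)})
        _, _, log = reduce_baseline(rec, cov, cfg=cfg)
        if len(log) > 1:
            assert (log["aic"].to_numpy() <= log["aic_before"].to_numpy()).all()
            assert log["aic"].is_monotonic_decreasing


class TestForwardDiscover:
    def test_single_candidate_reduces_to_threshold_test(self, cfg):
        rng = np.random.default_rng(51)
        rec, design = _survival_cohort(rng)
        base = design[["noise1"]]
        comp = design[["x"]].rename(columns={"x": "P_PC1"})
        trace = forward_discover(rec, base, comp, cfg)
        assert len(trace.steps) >= 1
        assert len(trace.steps[0]) == 1
        p_adj = trace.steps[0]["p_adj"].iloc[0]
        assert (len(trace.selected) == 1) == (p_adj < cfg.fdr_level)

    def test_causal_component_found_and_stop_rule_holds(self, cfg):
        rng = np.random.default_rng(52)
        rec, design = _survival_cohort(rng, n=600)
        base = pd.DataFrame(index=design.index)
        base["bmi_like"] = rng.standard_normal(len(design))
        comps = design[["x", "noise1", "noise2"]]
        trace = forward_discover(rec, base, comps, cfg)
        assert trace.selected[0] == "x"
        # every step's candidate table covers all then-remaining candidates
        assert len(trace.steps[0]) == 3
        last = trace.steps[-1]
        assert (last["p_adj"] >= cfg.fdr_level).all()

    def test_fdr_zero_selects_nothing_in_single_step(self):
        cfg0 = RunConfig(fdr_level=1e-12)
        rng = np.random.default_rng(53)
        rec, design = _survival_cohort(rng, n=100, beta_x=0.0)
        trace = forward_discover(rec, design[["noise1"]],
                                 design[["x", "noise2"]], cfg0)
        assert trace.selected == []
        assert len(trace.steps) == 1
        assert len(trace.steps[0]) == 2

    def test_zero_variance_candidate_rejected(self, cfg):
        rng = np.random.default_rng(54)
        rec, design = _survival_cohort(rng, n=50)
        comps = design[["x"]].copy()
        comps["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            forward_discover(rec, design[["noise1"]], comps, cfg)


class TestSingleMetaboliteScan:
    def test_one_row_per_metabolite_and_null_calibration(self, cfg):
        rng = np.random.default_rng(61)
        rec, design = _survival_cohort(rng, n=300, beta_x=0.0)
        mets = pd.DataFrame(rng.standard_normal((300, 40)),
                            index=design.index,
                            columns=[f"M{j}" for j in range(40)])
        out = single_metabolite_scan(rec, design[["noise1"]], mets, cfg)
        assert len(out) == 40
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p"] < 0.05).sum() <= 7          # ~5% of 40 under the null

    def test_causal_metabolites_rank_first(self, cfg):
        rng = np.random.default_rng(62)
        rec, design = _survival_cohort(rng, n=500, beta_x=0.6)
        mets = pd.DataFrame(rng.standard_normal((500, 20)),
                            index=design.index,
                            columns=[f"M{j}" for j in range(20)])
        # two metabolites proxy the causal covariate
        mets["M0"] = design["x"] + 0.3 * rng.standard_normal(500)
        mets["M1"] = design["x"] + 0.3 * rng.standard_normal(500)
        out = single_metabolite_scan(rec, design[["noise1"]], mets, cfg)
        top2 = set(out.nsmallest(2, "p")["metabolite_id"])
        assert top2 == {"M0", "M1"}


class TestDescriptiveTable:
    def _tables(self, rng, n=120, shift=0.0):
        cov = pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "bmi": rng.normal(26, 4, n),
            "smoking": rng.choice(["never", "former", "current"], n),
            "education": rng.choice(["low", "intermediate", "high"], n),
            "residency": rng.choice(["rural", "town", "city", "unknown"], n),
            "time_of_day": rng.choice(["before10", "h10to15", "after15"], n),
            "birth_date": pd.Timestamp("1950-01-01"),
            "sample_date": pd.Timestamp("2005-01-01"),
            "death_date": pd.NaT,
            "followup_end": pd.Timestamp("2021-12-31"),
        })
        klass = np.where(np.arange(n) % 3 == 0, "incident_case",
                         np.where(np.arange(n) % 3 == 1, "control",
                                  "prevalent_case"))
        cov.loc[klass == "incident_case", "bmi"] += shift
        assign = pd.DataFrame({"person_id": cov["person_id"], "klass": klass,
                               "first_qualifying_date": pd.NaT,
                               "rule_fired": ""})
        return cov, assign

    def test_identical_groups_welch_p_near_one(self, cfg):
        rng = np.random.default_rng(71)
        cov, assign = self._tables(rng)
        cov["bmi"] = 25.0
        cov.loc[assign["klass"] == "incident_case", "bmi"] = \
            np.tile([24.0, 26.0], 20)
        cov.loc[assign["klass"] == "control", "bmi"] = np.tile([24.0, 26.0], 20)
        out = descriptive_table(cov, assign).set_index("variable")
        assert out.loc["bmi (mean)", "p_incident_vs_control"] == pytest.approx(
            1.0, abs=1e-9)

    def test_welch_matches_textbook_formula(self, cfg):
        rng = np.random.default_rng(72)
        cov, assign = self._tables(rng, shift=2.0)
        out = descriptive_table(cov, assign).set_index("variable")
        i = cov.loc[assign["klass"] == "incident_case", "bmi"]
        c = cov.loc[assign["klass"] == "control", "bmi"]
        se2 = i.var(ddof=1) / len(i) + c.var(ddof=1) / len(c)
        tstat = (i.mean() - c.mean()) / np.sqrt(se2)
        df = se2**2 / ((i.var(ddof=1) / len(i))**2 / (len(i) - 1)
                       + (c.var(ddof=1) / len(c))**2 / (len(c) - 1))
        p = 2 * stats.t.sf(abs(tstat), df)
        assert out.loc["bmi (mean)", "p_incident_vs_control"] == pytest.approx(p)

    def test_chi_squared_hand_formula_2x2(self):
        table = np.array([[20, 10], [10, 20]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(6.667, abs=1e-3)
        assert p == pytest.approx(0.0098, abs=2e-4)

    def test_sex_test_uses_pearson_chi_squared(self, cfg):
        rng = np.random.default_rng(73)
        cov, assign = self._tables(rng)
        out = descriptive_table(cov, assign)
        sex_rows = out[out["variable"].str.startswith("sex=")]
        i = cov.loc[assign["klass"] == "incident_case", "sex"]
        c = cov.loc[assign["klass"] == "control", "sex"]
        tab = np.array([[(i == "male").sum(), (i == "female").sum()],
                        [(c == "male").sum(), (c == "female").sum()]])
        _, p, _, _ = stats.chi2_contingency(tab, correction=False)
        assert sex_rows["p_incident_vs_control"].dropna().iloc[0] == \
            pytest.approx(p)


class TestReplication:
    def test_two_platform_replication_concordant(self, cfg, tmp_path):
        # same latent biology, different platform scaling and noise
        d1 = SimulationDesign(n_people=500, n_pathways=4,
                              metabolites_per_pathway=12, beta_pathway=0.6,
                              n_xenobiotics=10, seed=201)
        study = simulate_study(d1)
        res = run_discovery(*study[:5], cfg, tmp_path / "disc", seed=201)
        assert res.trace.selected, "discovery must select a component"
        d2 = SimulationDesign(n_people=500, n_pathways=4,
                              metabolites_per_pathway=12, beta_pathway=0.6,
                              n_xenobiotics=10, seed=202)
        m2, ann2, defs2, ev2, cov2, _ = simulate_study(d2)
        # platform shift: rescale intensities metabolite-wise
        m2.values *= np.exp(np.linspace(-0.5, 0.5, m2.values.shape[1]))
        report = run_replication(res, study[1], m2, ann2, ev2, cov2, cfg,
                                 tmp_path / "repl")
        assert len(report) >= 1
        best = report.nsmallest(1, "p").iloc[0]
        assert best["p"] < 0.05
        assert best["direction_concordance"] == 1.0

    def test_pure_noise_replication_not_significant(self, cfg, tmp_path):
        d1 = SimulationDesign(n_people=500, n_pathways=4,
                              metabolites_per_pathway=12, beta_pathway=0.6,
                              n_xenobiotics=10, seed=203)
        study = simulate_study(d1)
        res = run_discovery(*study[:5], cfg, tmp_path / "disc", seed=203)
        d2 = SimulationDesign(n_people=500, n_pathways=4,
                              metabolites_per_pathway=12, beta_pathway=0.0,
                              n_xenobiotics=10, seed=204)
        m2, ann2, defs2, ev2, cov2, _ = simulate_study(d2)
        report = run_replication(res, study[1], m2, ann2, ev2, cov2, cfg,
                                 tmp_path / "repl")
        assert (report["p"] > 0.01).all()

    def test_self_replication_reproduces_discovery_hr(self, cfg, tmp_path):
        study = simulate_study(SimulationDesign(n_people=400, n_pathways=4,
                                                metabolites_per_pathway=12,
                                                beta_pathway=0.6,
                                                n_xenobiotics=10, seed=205))
        matrix, ann, defs, events, cov, _ = study
        res = run_discovery(matrix, ann, defs, events, cov, cfg,
                            tmp_path / "disc", seed=205)
        report = run_replication(res, ann, matrix, ann, events, cov, cfg,
                                 tmp_path / "repl")
        sel = res.trace.selected[0]
        disc_hr = res.trace.steps[0].set_index("candidate").loc[sel, "hr"]
        pc_index = int(sel.rsplit("_PC", 1)[1])
        row = report[report["pc_index"] == pc_index].iloc[0]
        assert row["hr"] == pytest.approx(disc_hr, abs=1e-8)
        assert row["direction_concordance"] == 1.0
        assert row["cosine_similarity"] == pytest.approx(1.0, abs=1e-9)
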