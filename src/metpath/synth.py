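"""Synthetic study generator with known ground truth.

Emulates the structure the pipeline consumes, end to end:

* **Metabolites** — pathway-block latent factors: each pathway ``j`` has a
  standard-normal factor ``f_j`` per person, and every member log-metabolite
  is ``mu_m + loading * f_j + noise_sd * eps``. Log-values are exponentiated
  to intensities; cells below each metabolite's ``missing_censor_quantile``
  are blanked (left-censored, missing-not-at-random). Chemical xenobiotics
  (own weak factor), a few microbial xenobiotics, and unannotated noise
  metabolites are appended. Pathway definitions cover the members plus a
  catch-all ``hsa01100`` super-pathway used to exercise the exclusion rule.
* **Event times** — a proportional-hazards model on the age scale with an
  exponential baseline, log-hazard ``beta_bmi * (BMI - mean) +
  beta_pathway * f_causal``. Onset beyond the entry age is sampled exactly
  by inversion (memorylessness); death and administrative censoring at
  ``admin_censor_age`` compete.
* **EHR streams** — incident persons receive two hypertension diagnoses at
  least 183 days apart starting at onset plus an antihypertensive
  prescription; prevalent persons the same pattern before the sample date;
  uncertain persons a single diagnosis or an elevated blood-pressure
  reading; excluded persons no events; controls an unremarkable
  blood-pressure reading (a tenth also a beta-blocker prescription without
  any diagnosis, which must stay control-eligible).

All randomness flows from ``design.seed`` through spawned generators; no
global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import MetaboliteMatrix

_XENO_LOADING = 0.4
_XENO_NOISE = 1.0
_BMI_MEAN = 26.0
_BMI_SD = 5.0


@dataclass
class SimulationDesign:
    n_people: int = 800
    n_pathways: int = 10
    metabolites_per_pathway: int = 12
    n_unannotated: int = 15
    n_xenobiotics: int = 12
    n_microbial_xenobiotics: int = 3
    within_pathway_loading: float = 0.7
    noise_sd: float = 0.6
    missing_censor_quantile: float = 0.10
    causal_pathway_index: int = 0
    beta_pathway: float = 0.3                     # per SD of the latent factor
    beta_bmi: float = math.log(1.10)              # per kg/m^2
    baseline_hazard: float = 0.025                # per year, age scale
    entry_age_range: tuple[float, float] = (40.0, 60.0)
    admin_censor_age: float = 70.0
    frac_prevalent: float = 0.30
    frac_uncertain: float = 0.03
    frac_exclude: float = 0.05
    frac_death: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("degenerate design: need at least one pathway")
        if not 0 <= self.causal_pathway_index < self.n_pathways:
            raise ValueError("causal_pathway_index must index an existing pathway")
        for name in ("frac_prevalent", "frac_uncertain", "frac_exclude",
                     "frac_death", "missing_censor_quantile"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.frac_prevalent + self.frac_uncertain + self.frac_exclude >= 1:
            raise ValueError("class fractions must sum below 1")
        if not 0 <= self.within_pathway_loading < 1:
            raise ValueError("within_pathway_loading must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        lo, hi = self.entry_age_range
        if not lo < hi <= self.admin_censor_age:
            raise ValueError("need entry_age_range low < high <= admin_censor_age")


@dataclass
class GroundTruth:
    classes: pd.DataFrame          # person_id, true_class, onset_age
    factors: pd.DataFrame          # person x pathway latent factors
    xeno_factor: pd.Series
    design: SimulationDesign


def _person_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def simulate_metabolites(
    design: SimulationDesign,
) -> tuple[MetaboliteMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Metabolite matrix + annotation + pathway definitions + ground truth."""
    rng = np.random.default_rng([design.seed, 0])
    n = design.n_people
    persons = _person_ids(n)
    factors = rng.standard_normal((n, design.n_pathways))
    xeno_factor = rng.standard_normal(n)

    met_ids: list[str] = []
    ann_rows: list[dict] = []
    def_rows: list[dict] = []
    log_cols: list[np.ndarray] = []
    compound_counter = 1

    def next_compound() -> str:
        nonlocal compound_counter
        cid = f"C{compound_counter:05d}"
        compound_counter += 1
        return cid

    for j in range(design.n_pathways):
        pid = f"hsa9{j:04d}"
        pname = f"Synthetic pathway {j}"
        for k in range(design.metabolites_per_pathway):
            mid = f"M{len(met_ids):04d}"
            cid = next_compound()
            mu = rng.normal(5.0, 1.0)
            col = (mu + design.within_pathway_loading * factors[:, j]
                   + design.noise_sd * rng.standard_normal(n))
            met_ids.append(mid)
            log_cols.append(col)
            ann_rows.append({"metabolite_id": mid, "name": f"metab_{mid}",
                             "kegg_compound_id": cid, "superpathway": "metabolism",
                             "xenobiotic_origin": "none"})
            def_rows.append({"pathway_id": pid, "name": pname,
                             "kegg_compound_id": cid})
        # two unmeasured compounds per pathway: definitions exceed the assay
        for _ in range(2):
            def_rows.append({"pathway_id": pid, "name": pname,
                             "kegg_compound_id": next_compound()})

    for _ in range(design.n_xenobiotics):
        mid = f"M{len(met_ids):04d}"
        mu = rng.normal(5.0, 1.0)
        col = (mu + _XENO_LOADING * xeno_factor
               + _XENO_NOISE * rng.standard_normal(n))
        met_ids.append(mid)
        log_cols.append(col)
        ann_rows.append({"metabolite_id": mid, "name": f"xeno_{mid}",
                         "kegg_compound_id": np.nan, "superpathway": "xenobiotics",
                         "xenobiotic_origin": "chemical"})
    for _ in range(design.n_microbial_xenobiotics):
        mid = f"M{len(met_ids):04d}"
        col = rng.normal(5.0, 1.0) + rng.standard_normal(n)
        met_ids.append(mid)
        log_cols.append(col)
        ann_rows.append({"metabolite_id": mid, "name": f"microbial_{mid}",
                         "kegg_compound_id": np.nan, "superpathway": "xenobiotics",
                         "xenobiotic_origin": "microbial"})
    for _ in range(design.n_unannotated):
        mid = f"M{len(met_ids):04d}"
        col = rng.normal(5.0, 1.0) + rng.standard_normal(n)
        met_ids.append(mid)
        log_cols.append(col)
        ann_rows.append({"metabolite_id": mid, "name": f"unknown_{mid}",
                         "kegg_compound_id": np.nan, "superpathway": "unannotated",
                         "xenobiotic_origin": "none"})

    # catch-all super-pathway over every defined compound (exclusion fixture)
    all_compounds = sorted({r["kegg_compound_id"] for r in def_rows})
    for cid in all_compounds:
        def_rows.append({"pathway_id": "hsa01100", "name": "Metabolic pathways",
                         "kegg_compound_id": cid})

    values = np.exp(np.column_stack(log_cols))
    if design.missing_censor_quantile > 0:
        cuts = np.quantile(values, design.missing_censor_quantile, axis=0)
        values = np.where(values < cuts, np.nan, values)
    df = pd.DataFrame(values, index=pd.Index(persons, name="person_id"),
                      columns=met_ids)

    # sampling timestamps; the hour drives the time-of-day category later
    sample_dates = pd.Timestamp("2003-01-01") + pd.to_timedelta(
        rng.integers(0, 15 * 365, size=n), unit="D")
    hours = rng.choice([9, 11, 16], size=n, p=[0.25, 0.53, 0.22])
    sample_dt = pd.Series(sample_dates + pd.to_timedelta(hours, unit="h"),
                          index=df.index, name="sample_datetime")

    truth = GroundTruth(
        classes=pd.DataFrame({"person_id": persons,
                              "true_class": "", "onset_age": np.nan}),
        factors=pd.DataFrame(factors, index=df.index,
                             columns=[f"factor_{j}" for j in range(design.n_pathways)]),
        xeno_factor=pd.Series(xeno_factor, index=df.index),
        design=design,
    )
    matrix = MetaboliteMatrix(df, sample_dt)
    ann = pd.DataFrame(ann_rows)
    defs = pd.DataFrame(def_rows)
    return matrix, ann, defs, truth


def simulate_cohort(
    design: SimulationDesign,
    truth: GroundTruth,
    sample_datetime: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """EHR events + covariates consistent with the latent ground truth."""
    rng = np.random.default_rng([design.seed, 1])
    n = design.n_people
    persons = list(truth.factors.index)
    f_causal = truth.factors.iloc[:, design.causal_pathway_index].to_numpy()

    entry_age = rng.uniform(*design.entry_age_range, size=n)
    bmi = np.clip(rng.normal(_BMI_MEAN, _BMI_SD, size=n), 16.0, 50.0)
    sex = rng.choice(["male", "female"], size=n, p=[0.38, 0.62])
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.55, 0.2, 0.25])
    education = rng.choice(["low", "intermediate", "high"], size=n, p=[0.1, 0.5, 0.4])
    residency = rng.choice(["rural", "town", "city", "unknown"], size=n,
                           p=[0.33, 0.10, 0.47, 0.10])

    sample_date = pd.to_datetime(sample_datetime.loc[persons]).dt.normalize()
    tod = pd.Series(
        pd.to_datetime(sample_datetime.loc[persons]).dt.hour, index=persons
    ).map(lambda h: "before10" if h < 10 else ("h10to15" if h <= 15 else "after15"))

    birth_date = sample_date - pd.to_timedelta(
        np.round(entry_age * 365.25).astype(int), unit="D")
    followup_end = birth_date + pd.to_timedelta(
        int(round(design.admin_censor_age * 365.25)), unit="D")

    # class layout: exclude / uncertain / prevalent drawn independently of
    # the hazard; the rest race onset against death and administrative censoring
    u = rng.random(n)
    c1 = design.frac_exclude
    c2 = c1 + design.frac_uncertain
    c3 = c2 + design.frac_prevalent
    death_age = np.where(rng.random(n) < design.frac_death,
                         entry_age + rng.exponential(30.0, size=n), np.inf)
    rate = design.baseline_hazard * np.exp(
        design.beta_bmi * (bmi - _BMI_MEAN) + design.beta_pathway * f_causal)
    onset_age = entry_age + rng.exponential(1.0 / rate, size=n)

    classes = np.empty(n, dtype=object)
    onset_out = np.full(n, np.nan)
    censor_age = np.minimum(design.admin_censor_age, death_age)
    for i in range(n):
        if u[i] < c1:
            classes[i] = "exclude"
        elif u[i] < c2:
            classes[i] = "uncertain"
        elif u[i] < c3:
            classes[i] = "prevalent_case"
            onset_out[i] = rng.uniform(max(18.0, entry_age[i] - 15.0),
                                       entry_age[i] - 1.0)
        elif onset_age[i] <= censor_age[i]:
            classes[i] = "incident_case"
            onset_out[i] = onset_age[i]
        else:
            classes[i] = "control"

    events_rows: list[dict] = []
    day = pd.Timedelta(days=1)
    uncertain_toggle = 0
    for i, pid in enumerate(persons):
        klass = classes[i]
        sd = sample_date.iloc[i]
        if klass == "exclude":
            continue
        if klass == "uncertain":
            if uncertain_toggle % 2 == 0:
                events_rows.append({"person_id": pid, "kind": "diagnosis",
                                    "code": "I10", "date": sd + 300 * day,
                                    "systolic": np.nan, "diastolic": np.nan})
            else:
                events_rows.append({"person_id": pid, "kind": "bp_measurement",
                                    "code": "", "date": sd,
                                    "systolic": 152.0, "diastolic": 88.0})
            uncertain_toggle += 1
            continue
        if klass in ("prevalent_case", "incident_case"):
            onset_date = birth_date.iloc[i] + pd.Timedelta(
                days=int(round(onset_out[i] * 365.25)))
            if klass == "incident_case":
                d1 = max(onset_date, sd + day)
            else:
                d1 = min(onset_date, sd - 400 * day)
            gap = int(rng.integers(183, 400))
            code = rng.choice(["I10", "I11.0", "I12.0", "I13"])
            events_rows.append({"person_id": pid, "kind": "diagnosis",
                                "code": code, "date": d1,
                                "systolic": np.nan, "diastolic": np.nan})
            events_rows.append({"person_id": pid, "kind": "diagnosis",
                                "code": "I10", "date": d1 + gap * day,
                                "systolic": np.nan, "diastolic": np.nan})
            events_rows.append({"person_id": pid, "kind": "prescription",
                                "code": "C03AA03", "date": d1 + 30 * day,
                                "systolic": np.nan, "diastolic": np.nan})
            continue
        # control: unremarkable blood pressure; some also get a beta-blocker
        # prescription with no hypertension diagnosis (must stay control)
        events_rows.append({"person_id": pid, "kind": "bp_measurement",
                            "code": "", "date": sd,
                            "systolic": float(rng.integers(100, 139)),
                            "diastolic": float(rng.integers(65, 89))})
        if rng.random() < 0.10:
            events_rows.append({"person_id": pid, "kind": "prescription",
                                "code": "C07AB02", "date": sd + 100 * day,
                                "systolic": np.nan, "diastolic": np.nan})

    events = pd.DataFrame(events_rows,
                          columns=["person_id", "kind", "code", "date",
                                   "systolic", "diastolic"])
    death_date = pd.Series(pd.NaT, index=persons)
    recorded = (death_age < design.admin_censor_age)
    death_days = np.round(np.where(np.isinf(death_age), 0, death_age) * 365.25)
    for i, pid in enumerate(persons):
        if recorded[i]:
            # day rounding must never push death before the sample date
            death_date.iloc[i] = max(
                birth_date.iloc[i] + pd.Timedelta(days=int(death_days[i])),
                sample_date.iloc[i] + pd.Timedelta(days=1),
            )
    covariates = pd.DataFrame({
        "person_id": persons,
        "sex": sex, "bmi": bmi, "smoking": smoking, "education": education,
        "residency": residency, "time_of_day": tod.values,
        "birth_date": birth_date.values, "sample_date": sample_date.values,
        "death_date": death_date.values, "followup_end": followup_end.values,
    })
    truth_out = GroundTruth(
        classes=pd.DataFrame({"person_id": persons, "true_class": classes,
                              "onset_age": onset_out}),
        factors=truth.factors, xeno_factor=truth.xeno_factor, design=design,
    )
    return events, covariates, truth_out


def simulate_study(design: SimulationDesign):
    """Convenience wrapper: full synthetic study from one design.

    Returns (matrix, annotation, pathway definitions, events, covariates,
    ground truth).
    """
    matrix, ann, defs, truth = simulate_metabolites(design)
    events, covariates, truth = simulate_cohort(design, truth,
                                                matrix.sample_datetime)
    return matrix, ann, defs, events, covariates, truth
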