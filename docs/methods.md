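# Methods

## The problem

High-dimensional metabolomics (1000+ features) against a few hundred
analysable persons makes single-feature survival scans underpowered and
hard to interpret, and metabolite panels differ between assay platforms,
which frustrates replication. `metpath` implements a pathway-level
alternative: reduce the metabolite matrix to a handful of KEGG-pathway
principal components, phenotype incident hypertension from routine EHR
streams, and search those components for association with time to
diagnosis using left-truncated Cox models on the age timescale.

## Pre-processing

The input matrix holds volume-normalised, non-imputed intensities.
Pipeline order is fixed and each step is strict about its boundary
semantics:

1. drop metabolites missing in **strictly more than** 20% of persons;
2. drop persons missing **strictly more than** 50% of metabolites
   (applied after the metabolite filter; on realistic data this is usually
   an identity transform);
3. resolve repeat samples to the chronologically **earliest** draw
   (identical timestamps are an error, not a tie-break);
4. replace each remaining missing cell with **half the metabolite's
   observed minimum** — the standard convention for left-censored,
   below-detection intensities; imputation runs on the pre-log scale and
   never touches an observed value;
5. natural-log transform.

Duplicate resolution precedes imputation so imputation minima are computed
on the analysis set. Persons missing BMI, smoking status or time of day
are removed (complete-case rule); no covariate is imputed.

## Pathway components

Metabolites with KEGG compound ids are mapped into pathways via a
user-replaceable pathway definition table (a small snapshot ships in
`src/metpath/data/kegg_fixture.tsv`; the format is three columns:
pathway_id, name, kegg_compound_id). The global "Metabolic pathways"
roll-up (hsa01100) and the nucleotide-metabolism roll-up (hsa01232) are
excluded because their members are already covered by their sub-pathways.
Pathways with at least 10 matched metabolites qualify. Chemical
(non-microbial) xenobiotics map to no human pathway and are pooled into
one extra PCA group, handled under exactly the same component rules.
Unannotated metabolites and metabolites in no qualifying pathway reach
only the single-metabolite scan, never a component.

Per pathway, PCA is computed on the **correlation** matrix (z-scored
metabolites). The scaling choice is ours: log-intensities have
heterogeneous variances across assays, and correlation-PCA makes component
scores comparable across pathways; `pca_scale: covariance` switches to
unscaled PCA. At most three components are considered. A trailing
component is dropped when its variance-explained gain is below five
percentage points, hierarchically (losing PC2 also loses PC3, preserving
"first k components" semantics). Component sign is fixed deterministically:
the largest-|loading| metabolite loads positively, ties broken by the
lexicographically smallest metabolite id.

Cross-pathway component pairs with |Pearson r| strictly above 0.9 are
pruned: pairs are processed in descending |r| (deterministic tie-break on
component names), and the component from the pathway with fewer matched
metabolites is removed (size ties: the lexicographically larger pathway id
loses). Within-pathway pairs are orthogonal by construction and never
tested. The default removes the offending *component*; `prune_unit:
pathway` removes the whole pathway instead, for sensitivity analyses.

## Phenotyping

A person is a **case** given two hypertension diagnoses (ICD-10 I10–I13,
matched by prefix on dot-stripped codes) at least 183 days apart, or one
such diagnosis plus an antihypertensive prescription (ATC C02–C09, any
temporal order). The earliest hypertension diagnosis dates the case;
cases dated on or before the sample date are prevalent (the condition
predates the draw), later ones incident. Non-cases are **uncertain** given
a single hypertension diagnosis date, a hypertension-adjacent code
(O10–O16, R03.0, H35.0, I67.4, I15), or any blood-pressure reading
strictly over 140 mmHg systolic or 90 mmHg diastolic. Persons with no EHR
events at all are **excluded**; everyone else is a **control**.

Deliberate edge decisions (all verified by an enumerated truth-table
test): case rules take precedence over uncertain codes; prescription-only
persons are eligible controls (both case rows require a diagnosis) and
their count is logged; duplicate event rows never change a class (the
"single diagnosis" rule counts distinct dates); a reading of exactly
140/90 is not "over" the cut-offs; "6 months" is a fixed 183 calendar days
to stay month-length independent. All of these are configurable.

## Survival analysis

Ages are calendar-day differences divided by 365.25. Entry is the age at
sampling; exit is the minimum of diagnosis age, death age and
follow-up-end age; the event fires only when an incident case exits at
diagnosis. Only incident cases and controls are analysable.

`fit_cox` maximises the left-truncated Efron partial likelihood by
Newton–Raphson with analytic gradient and Hessian, step-halving, and
convergence at gradient norm < 1e-9 (the risk set at event age *u* is
`{i : entry_i < u <= exit_i}`). Efron tie handling is the default, which
matters because day-resolution dates produce tied event ages. Covariates
are centred internally for numerical stability (coefficients are
invariant); categorical covariates expand against fixed reference levels
(never / male / rural / low / before-10). Diverging coefficients (monotone
likelihood) and rank-deficient designs raise rather than returning
garbage. Standard errors come from the observed information; candidate
p-values are Wald. AIC is −2·logPL + 2·#coefficients.

Proportional hazards are checked by the classical scaled-Schoenfeld score
test: Efron-weighted per-event residuals correlated against event age
(identity time transform), chi-squared per term and globally. The test's
variance uses the average per-event information — the standard first-order
approximation; calibration simulations in the test suite confirm ~5%
type-I error under proportional hazards and high power against a
sign-flipping effect.

The **baseline model** starts from sex, BMI, smoking, education, residency
and time of day and is reduced by iterated drop-one elimination: all
single-term-dropped models are fitted, the likelihood-ratio chi-square of
each drop is logged, and the drop yielding the lowest AIC is taken while
it improves on the current model. Categorical terms drop as whole blocks.

**Forward discovery** then fits, at each step, one model per remaining
pathway component (baseline + already-selected + candidate), collects the
candidates' Wald p-values, applies Benjamini–Hochberg **within the step's
candidate set**, and admits the smallest adjusted p if it is below the FDR
level (0.05); ties break to the smaller raw p, then column order. BH is
deliberately not pooled across steps — each step is one family of
candidate models. The **single-metabolite scan** fits baseline + one
metabolite per model with the same BH correction, flagging significant
hits whose model fails the proportionality check.

**Replication** matches the discovered pathway's metabolites to a second
platform by KEGG compound id, re-runs pre-processing and pathway PCA on
the replication matrix (all `pc_cap` components, since component order
need not transfer across platforms), re-reduces the baseline on the
replication covariates, and tests each recomputed PC separately. The
report includes the cosine similarity between recomputed and discovery
loading vectors on the overlap and the sign-aligned direction concordance.
With the replication cohort set equal to the discovery cohort this
reproduces the discovery component's hazard ratio exactly.

## Synthetic cohorts

Because the motivating study's person-level biobank records are not
distributable, all development and validation run on synthetic cohorts
with known ground truth.

*Metabolites.* Pathway *j* has a standard-normal latent factor *f_j* per
person; each member log-metabolite is `mu_m + 0.7·f_j + 0.6·eps`
(within-pathway correlation ≈ 0.58, a moderate, realistic block
structure), exponentiated to intensities with metabolite-specific
baselines `mu_m ~ N(5, 1)`. Per metabolite, cells below the empirical 10%
quantile are blanked — left-censored, missing-not-at-random, matching
below-detection dropout. Chemical xenobiotics share a weak factor
(loading 0.4) so the pooled xenobiotic group retains several components;
microbial xenobiotics and unannotated metabolites are independent noise.

*Events.* Onset age follows an exponential baseline hazard on the age
scale (0.025/year) scaled by `exp(log(1.10)·(BMI−26) + 0.3·f_causal)`,
sampled exactly beyond the entry age by inversion (memorylessness). Entry
ages are uniform on 40–60; administrative censoring at age 70; 10% of
persons draw a competing death age. The implied cumulative incidence over
ages 40–70 (roughly 40–50%) matches realistic hypertension risk and
yields about 200 incident events per 800-person cohort. Class fractions
(30% prevalent, 3% uncertain, 5% event-free) mirror the stratum structure
of a volunteer biobank subcohort. Prevalent cases and death are not part
of the spec'd hazard mechanism, so the generator assigns prevalence
independently of the hazard and renders its onset before the sample date —
a deliberate simplification; prevalent persons never enter the survival
data, so this cannot bias the analysable strata.

*EHR rendering.* Incident/prevalent persons receive two hypertension
diagnoses ≥183 days apart plus a prescription; uncertain persons a single
diagnosis or an elevated reading; excluded persons nothing; controls an
unremarkable blood-pressure reading, a tenth of them also a beta-blocker
prescription with no diagnosis (which must remain control-eligible).
Covariate categories draw from distributions spanning the ranges typical
of biobank questionnaires; the time-of-day category is derived from the
sampling timestamp's hour.

All randomness flows from a single design seed through spawned
generators; nothing touches global RNG state, and identically-seeded runs
are byte-identical.

*What the generator does not emulate:* batch and drift effects, realistic
metabolite identities and concentration scales, correlated missingness
across metabolites, coding noise and transfers in real EHR streams,
informative (health-related) censoring, or covariate-dependent class
membership for prevalent/uncertain/excluded persons. Passing tests
therefore demonstrate correctness of the algorithms and calibration under
the stated model, not robustness to real-data artefacts.

## Problem sizes and numerical choices

The reference recovery design uses 800 persons and 10 pathways × 12
metabolites; calibration experiments run 25 recovery seeds and 100 null
seeds, with the single-metabolite scan on a 10-seed subset — sizes chosen
to give stable rates while keeping the full suite fast. Newton tolerance
is 1e-9 on the gradient norm; PCA is computed by SVD of the standardised
data (equivalent to the correlation-matrix eigendecomposition to ~1e-14);
BH adjustment is the exact step-up formula. Degenerate inputs
(zero-variance metabolites or components, all-missing metabolites,
separated Cox designs, identical duplicate timestamps, empty strata) all
raise typed errors with the offending entity named.

## Known limitations

* The Schoenfeld test uses the averaged-information approximation rather
  than the refitting estimator of newer `survival::cox.zph` versions;
  p-values agree closely but not exactly with R's current implementation.
* Two diagnoses less than six months apart with no other signal classify
  as control (the uncertain rules enumerate only the single-diagnosis
  case); arguably such persons carry some disease signal.
* The replication harness assumes compound-id overlap is a faithful
  cross-platform match; isomer-level ambiguity is not modelled.
* `reduce_baseline` iterates drop-one elimination to an AIC minimum; a
  single-pass variant is not provided.
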