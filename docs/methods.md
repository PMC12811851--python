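# Methods

This note documents the statistical procedures, the synthetic-data model, the
numerical choices, and the limitations of `alriscore`.

## Scores as data

Every score is a list of components; each component names a deterministic
*extractor* (admission fields → category) and a category → integer points
table. The engine validates, at load time, that every category in an
extractor's range has a point value, that component ids are unique, and that
the declared theoretical minimum/maximum equal the sums of per-component
extrema. The eight bundled definitions in `data/score_definitions.yaml` are
transcriptions of the original score publications adapted to the fields of a
retrospective admission dataset:

- Items such a dataset cannot assess at all (ReSVinet's apnea, medical
  intervention and fever grading; PERCH's grunting and illness duration;
  mRISC's night sweats and laboratory-confirmed malaria items) are declared in
  `unavailable_components` and contribute nothing, mirroring how partial
  scores are evaluated in practice. Theoretical ranges are therefore over the
  assessable components.
- Graded ReSVinet items are encoded as deterministic category extractors over
  the available fields (feeding intolerance from "unable to drink" / "vomits
  everything"; respiratory difficulty from cyanosis, chest indrawing, nasal
  flaring and head nodding; general condition from the recorded conscious
  level). Mild presentations that routinely collected signs cannot
  distinguish map to the reference (0-point) category.
- "Refusal to feed" style items are evaluated through the recorded
  "unable to drink" flag.

The nutrition-augmented ReSVinet adds one component: +2 points for moderate
and +3 for severe malnutrition. Three variants exist (MUAC, weight-for-age,
weight-for-length); the bundled definition uses MUAC and the other two are
available through `compute_modified_resvinet`.

**Missing data.** Under policy `fail` a record missing any required field of
any component aborts with an error naming the component and field
(complete-case analysis). Under policy `skip` the affected component
contributes 0 and is listed in `components_skipped_missing`; structurally
unavailable components are tracked separately in the definition. The two
policies agree exactly on complete records (property-tested).

## Thresholds

Malnutrition categories use strict less-than on the lower side: MUAC < 11.5 cm
severe, < 12.5 cm moderate; z-scores < −3 severe, < −2 moderate — so a
z-score of exactly −2 is normal and a MUAC of exactly 11.5 cm is moderate.
The fast-breathing cutoff is 40 breaths/min for ages 2–11 months and 50 from
12 months on; the 50 bpm rule is extended through 59 months so the wider
sensitivity cohort can be scored. Children under 2 months are outside every
score's intended range and the age-dependent extractors reject them.

## Cohorts and exclusion accounting

Cohort A (main analysis): ages 2–24 months inclusive, ALRI discharge
diagnosis, outcome death or discharge, complete data for the score fields
under evaluation. Sensitivity cohorts relax one rule each: B drops the
diagnosis requirement, C widens age to 2–59 months, D retains records with
missing fields (scored under policy `skip`), E excludes admissions in the
closed interval 13 Mar 2020 – 13 Mar 2021 (the first pandemic year), and F
keeps only admissions strictly before 13 Mar 2020.

Exclusion reasons apply in the fixed order age → diagnosis → missing data →
outcome → date; each record is counted under the first reason it triggers, so
tallies are deterministic and sum to the input size. The complete-case field
set is a parameter (derived from the scores under evaluation via
`required_fields_for`) rather than hard-coded; selecting the
nutrition-augmented ReSVinet pulls in all three malnutrition measures, because
its variant comparison needs them.

## Discrimination analysis

The AUROC is the Mann–Whitney estimator with midrank tie handling, computed
from sorted-array placement values in O(n log n); an O(n²) exhaustive
enumeration is kept in the tests as the oracle. Variance and the covariance
between two scores measured on the same subjects follow DeLong's structural
components: with placements `V10` (per case) and `V01` (per control),
`var = S10/m + S01/n` using sample (co)variances. Confidence intervals are
Wald on the AUROC scale, truncated to [0, 1]; no logit transform is applied.
The paired test is `z = (AUC_a − AUC_b)/√(var_a + var_b − 2 cov_ab)` with a
two-sided normal p-value and a significance flag fixed at p < 0.01; no
multiplicity correction is applied across pairwise comparisons. A zero pooled
variance with equal AUROCs returns z = 0, p = 1 by convention; with unequal
AUROCs it is reported as a degenerate-variance error.

Threshold tables classify `score ≥ cutoff` as high risk at every distinct
observed value (scores are integers, so no continuous sweep is needed),
and the optimal cutoff maximizes Youden's J with ties broken toward the
smaller cutoff. Stratified analyses run one independent DeLong analysis per
stratum and report, rather than raise on, strata lacking two subjects per
outcome class. Band labels are applied to unrounded AUROCs.

## Descriptive statistics

Crude odds ratios are 2×2 cross-products with Woolf log-scale intervals; zero
cells fail loudly by default, with the Haldane–Anscombe +0.5 correction
behind an explicit flag. Adjusted odds ratios come from one logistic fit per
exposure (death ~ exposure dummies + age band + sex, references: youngest
band, female), exponentiating the exposure coefficients — not one joint model
over all exposures. Whether age should enter as the three descriptive bands
or as continuous months is a genuinely open choice; the bands are used
because they match the descriptive table's own categorization.

The logistic fitter is an IRLS (Newton) solver: convergence when the
log-likelihood changes by < 1e−8, at most 25 iterations. Rank-deficient
designs raise an error naming the collinear columns (pivoted QR); complete
separation is detected (unbounded likelihood / runaway coefficients) and
reported as a distinct failure instead of returning a divergent estimate.
Constant dummy columns (e.g. sex in an all-male cohort) are dropped with a
warning, so a degenerate adjustment gracefully reduces to the crude estimate.
The table builder keeps unrounded values internally; presentation rounding is
half-away-from-zero to 1 decimal.

## Synthetic cohorts

`generate_cohort` draws each variable's category independently from the
configured prevalences, materializes continuous measurements uniformly inside
the chosen category's band (e.g. MUAC in [9.0, 11.45) for severe), and draws
death from `logit p = b0 + Σ β(variable, category)`. The intercept `b0` is
calibrated by bisection so the mean predicted probability over the drawn
covariates equals `target_cfr` (tolerance 1e−6; an unreachable target raises
a calibration error). Missingness is injected completely at random per field
— no mechanism is known for the kind of data being emulated, so MCAR is the
neutral default. Everything is a pure function of (config, seed).

The packaged `table1_like_config` sets prevalences from a published
descriptive table's overall column and coefficients from its age/sex-adjusted
odds ratios, with a 7% target case fatality rate over admissions dated
2015–2024. Because the outcome model is logistic in the categorized
covariates, the configured coefficients *are* the conditional odds ratios
that a correctly specified full logistic refit recovers — this is an exact,
testable contract (verified at n = 50 000 within sampling error).

Two properties of this design deserve emphasis:

- **Non-collapsibility.** An odds ratio adjusted only for age and sex is a
  partially marginalized quantity; with strong independent risk factors in
  the outcome model it is systematically attenuated relative to the
  conditional coefficient (for the default profile, the severe-MUAC
  conditional OR of 7.4 marginalizes to roughly 4–5). This is expected
  logistic-regression behaviour, not a defect; parameter-recovery tests
  therefore refit the full model, and crude estimates are compared against
  the generator's *marginal* ORs obtained by Monte-Carlo integration.
- **Independence of covariates.** Variables are drawn independently, whereas
  real malnutrition measures, vital signs and consciousness are strongly
  correlated. Synthetic AUROCs are therefore not estimates of any real
  score's discrimination; they exercise the machinery, not the epidemiology.
  `model_implied_auroc` provides the generator's own Monte-Carlo AUROC (the
  Bernoulli outcome is integrated out by weighting each profile with its
  death probability), and the empirical AUROC of a scored synthetic cohort is
  tested to agree with it within 0.02 at n = 20 000 / n_mc = 200 000.

`generate_flowchart_fixture` is the deterministic counterpart: 2261 eligible
admissions of which exactly 60 carry missing required fields (4 missing both
weight-derived z-scores, 16 missing weight-for-age only, 38 missing
weight-for-length only, 2 missing the "vomits everything" flag) and 19 have a
non-analysable outcome (5 absconded, 14 transferred). Within the 2182
analysable admissions (152 deaths), every descriptive variable is assigned
with *exact* outcome-stratified category counts taken from the published
descriptive table, shuffled independently across variables. Crude odds
ratios recomputed from the fixture therefore equal the published ones
identically, while joint distributions between variables are random — the
fixture validates accounting and estimation machinery, not multivariate
structure.

## Problem sizes

Heavy checks use n = 100 000 cohorts for calibration and marginal fidelity,
n = 50 000 for odds-ratio recovery, and n = 20 000 cohorts against an
n = 200 000 Monte-Carlo reference for AUROC recovery; these sizes put
sampling error well below the asserted tolerances while keeping the full
suite under a minute of compute.

## Limitations

- Score weights are transcribed from the original publications as adapted to
  this record vocabulary; users validating against a specific instrument
  should audit `data/score_definitions.yaml` (it is data, not code, and
  round-trips through `serialize_registry`).
- Weight-for-age and weight-for-length z-scores are inputs; the package does
  not compute them from raw anthropometry against growth-standard tables.
- Calibration of predicted risks (as opposed to discrimination) is out of
  scope, as is any HIV-positive score variant and the LIBSS bronchiolitis
  score.
- The synthetic generator has no seasonal or epidemic temporal structure;
  admission dates are uniform over the configured range.
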