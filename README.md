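# alriscore

A validation toolkit for **pediatric ALRI severity scores** — the point-based
clinical rules used in low-resource hospitals to flag young children admitted
with acute lower respiratory infection (pneumonia or bronchiolitis) who are at
high risk of dying in hospital.

The package is aimed at epidemiologists and clinical researchers who want to
externally validate such scores on admission-level cohorts, or to prototype
the analysis before real data are in hand. It bundles, as declarative data
rather than code, eight scores: RISC (HIV-negative), mRISC, RISC-Malawi in its
MUAC and weight-for-age variants, PERCH, PREPARE, ReSVinet, and a
nutrition-augmented ReSVinet that adds 2 points for moderate and 3 points for
severe malnutrition.

## What it computes

**Scoring.** Each score is a sum of integer component points. A component is a
deterministic mapping from admission fields (oxygen saturation, conscious
level, respiratory rate relative to the WHO age-specific cutoff of 40 bpm at
2–11 months and 50 bpm thereafter, MUAC / weight-for-age / weight-for-length
malnutrition categories with cutoffs 12.5 and 11.5 cm and −2 and −3 z, and a
vocabulary of binary clinical signs) into a category, and from that category
into points. Components with missing inputs either abort the record
(complete-case analysis) or contribute 0 and are recorded as skipped.

**Discrimination.** For score `S` and in-hospital death `D`, the package
estimates `AUROC = P(S_case > S_control) + ½·P(S_case = S_control)` by the
Mann–Whitney statistic with midrank ties, with variance, confidence intervals
and two-sided paired tests by DeLong's method on the per-subject placement
values. Thresholds are swept over all observed score values (`score ≥ c` =
high risk) reporting sensitivity, specificity, Youden `J = se + sp − 1`, the
high-risk fraction, and the observed case fatality rate in the high-risk
group; the "optimal" cutoff maximizes `J`. AUROCs are labeled with the usual
discrimination bands (< 0.50 none, 0.50–0.69 poor, 0.70–0.79 acceptable,
0.80–0.89 good, ≥ 0.90 excellent).

**Descriptives.** Outcome-stratified counts and percentages, crude odds ratios
from 2×2 cross-products with Woolf intervals
`exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`, and age/sex-adjusted odds ratios
from a maximum-likelihood logistic fit (hand-rolled IRLS with explicit
separation and rank-deficiency reporting).

**Synthetic cohorts.** A seeded generator draws covariate categories from
configurable prevalences and the outcome from a logistic model whose
coefficients are, by construction, the conditional odds ratios a full refit
should recover; the intercept is calibrated by bisection to a target case
fatality rate. A deterministic fixture reproduces a published inclusion flow
chart exactly (2261 admissions → 60 missing-data and 19 other-outcome
exclusions → 2182 analysable, 152 deaths).

## Worked example

```python
from alriscore import (
    STUDY_COHORTS, apply_cohort_filter, compute_score_matrix,
    delong_ci, generate_flowchart_fixture, load_score_definitions,
    required_fields_for, Outcome,
)

registry = load_score_definitions()
cohort = generate_flowchart_fixture(seed=1)
included, tally = apply_cohort_filter(
    cohort, STUDY_COHORTS["A"], required_fields_for(registry)
)
print(tally.as_dict())
matrix = compute_score_matrix(included, registry)
deaths = [r.outcome is Outcome.DIED for r in included]
roc = delong_ci(matrix["risc_malawi_muac"], deaths, score_id="risc_malawi_muac")
print(f"AUROC {roc.auroc:.3f} (95% CI {roc.ci95[0]:.3f}-{roc.ci95[1]:.3f}), {roc.band}")
```

prints

```
{'age_out_of_range': 0, 'no_alri_dx': 0, 'missing_data': 60, 'other_outcome': 19, 'date_excluded': 0, 'included': 2182}
AUROC 0.842 (95% CI 0.805-0.878), good
```

i.e. of 2261 eligible admissions, 60 are dropped for missing score inputs and
19 for absconding or transfer, leaving 2182 children (152 deaths, 7.0% case
fatality); on this synthetic cohort the MUAC variant of RISC-Malawi ranks the
children who died above the survivors with probability 0.84.

The same pipeline is available from the shell:

```bash
alriscore simulate --preset flowchart --seed 1 --out sim/
alriscore run --input sim/cohort.csv --cohort A --out reports/
alriscore compare --input sim/cohort.csv --score-a risc_malawi_muac --score-b resvinet
```

`run` writes the exclusion tally, the score matrix, a Table-1-style
descriptive CSV, per-score threshold tables, the optimal-cutoff summary and
the pairwise DeLong p-value matrix.

## Layout

- `src/alriscore/records.py` — admission records and cohort CSV I/O
- `src/alriscore/cohorts.py` — study cohorts A–F with exclusion accounting
- `src/alriscore/anthropometry.py` — malnutrition and vital-sign categories
- `src/alriscore/scoring.py` + `data/score_definitions.yaml` — the score engine
- `src/alriscore/evaluation.py` — AUROC, DeLong inference, threshold sweeps
- `src/alriscore/descriptives.py` — Table-1 builder, crude/adjusted ORs, IRLS
- `src/alriscore/synthetic.py` — cohort generator and flow-chart fixture
- `src/alriscore/cli.py` — the `alriscore` command
- `docs/methods.md` — modeling assumptions, numerical choices, limitations
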