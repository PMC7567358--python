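# mcds — drug-based comorbidity scoring for 1-year mortality

`mcds` implements a modified Chronic Disease Score: a comorbidity index that
predicts an individual's 1-year risk of death **from outpatient drug
prescriptions alone**, with no diagnosis codes. It is aimed at
pharmacoepidemiologists and health-services researchers who work with
administrative pharmacy-claims databases and need a morbidity measure for
risk stratification or case-mix adjustment when hospital discharge records
are unavailable or unreliable.

## The score

Chronic conditions are inferred from dispensed drugs: each condition *j* is
defined by a set of ATC-code prefixes and a minimum number of prescriptions
per calendar year in a two-year lookback window (2 per year as a general
rule, 1 for drugs that unambiguously identify a diagnosis, 3 for drugs also
frequent in minor, non-chronic conditions). Drug-level exceptions implement
clinical reassignments (for example midazolam counts toward epilepsy, not
toward the anxiolytic benzodiazepines).

Given the binary condition profile x = (x₁, …, x_K), the total score is

    S = Σⱼ wⱼ xⱼ,     wⱼ = round(10 · βⱼ),

where βⱼ are the condition coefficients of a multivariable Cox
proportional-hazards model for 1-year mortality. The shipped weight table
carries 18 weighted conditions (cancer 10, chronic renal disease 7,
psychosis 7, … liver diseases 1; maximum score 63). Patients are
stratified into six risk classes (score ≤1, 2, 3–4, 5–6, 7–9, ≥10).

The package covers the score's whole life cycle:

| module | what it does |
|---|---|
| `mcds.io` | read/validate/write claims, cohort and outcome tables; build (time, event) survival records with administrative censoring |
| `mcds.mapping` | ATC-pattern condition flagging with per-year thresholds, exceptions and a prevalence floor |
| `mcds.scoring` | the weight transform, total score, risk classes |
| `mcds.derivation` | weight re-derivation: LASSO-penalized Cox (Breslow ties), 10-fold cross-validated deviance, one-standard-error rule, unpenalized refit |
| `mcds.chaid` | ordinal CHAID tree to discover risk-class boundaries |
| `mcds.validation` | c-statistic with DeLong CI, paired DeLong score comparison, Kaplan–Meier by class, k-sample log-rank |
| `mcds.simulate` | synthetic claims/cohort/outcomes generator with known truth |

The shipped ATC mapping is a best-effort default (every row is marked
`unverified` in its provenance column): validate it against local
prescribing and reimbursement practice, and override it with
`mcds.load_mapping("your_mapping.csv")`.

## Worked example

```python
import mcds

bundle   = mcds.simulate_cohort(mcds.SimulationParams(n_patients=5000, seed=7))
profiles = mcds.map_conditions(bundle["claims"], bundle["cohort"]["patient_id"])
scores   = mcds.score_profiles(profiles)
```

Running `python examples/01_score_cohort.py` (the same steps) prints:

```
78508 prescriptions for 5000 patients
conditions flagged per patient: mean 2.17
score: mean 3.42, median 3, IQR [1-5], range [0-21]
  class 1 (score  <=1):  1305 patients (26.1%)
  class 2 (score    2):  1185 patients (23.7%)
  class 3 (score  3-4):  1105 patients (22.1%)
  class 4 (score  5-6):   723 patients (14.5%)
  class 5 (score  7-9):   387 patients (7.7%)
  class 6 (score >=10):   295 patients (5.9%)
```

Each patient's prescriptions were turned into condition flags, the flags
into an integer score (here averaging 3.42 points), and the score into one
of the six risk classes; higher classes carry more weighted chronic
conditions and a higher predicted 1-year mortality. The other example
scripts show weight re-derivation (`02`), CHAID boundary discovery (`03` —
on a 100,000-patient synthetic cohort it finds six classes close to the
shipped default) and discrimination/calibration-free validation (`04`).

A thin CLI wraps the same functions:

```sh
mcds simulate --n 100000 --seed 7 --outdir data
mcds score    --claims data/claims.csv --cohort data/cohort.csv --out scores.csv
mcds derive   --claims data/claims.csv --cohort data/cohort.csv \
              --outcomes data/outcomes.csv --seed 1 --out weights.csv
mcds stratify --scores scores.csv --cohort data/cohort.csv \
              --outcomes data/outcomes.csv --out scheme.json
mcds validate --scores scores.csv --cohort data/cohort.csv \
              --outcomes data/outcomes.csv --out report.json
```

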