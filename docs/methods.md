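# Methods

## Condition flagging

A condition rule is a set of ATC prefixes, a per-calendar-year minimum
prescription count, and optional full-code exceptions. A patient is flagged
when the count of matching claim rows reaches the threshold in **at least
one** of the two lookback years (2016 or 2017 by default); counts are not
pooled across years unless `pool_years=True` is requested. The per-year
reading follows the flagging convention stated with the original condition
list ("in the observed year"); pooling is strictly more permissive, so the
option exists for sensitivity analyses. Prescriptions are counted as claim
rows — not packages or defined daily doses — because the thresholds were
defined on prescription counts; a missing `n_packages` column therefore
costs nothing.

Thresholds come in three tiers: 2 per year as the general criterion, 1 for
drugs that unambiguously identify the diagnosis (e.g. multiple-sclerosis
disease-modifying agents), 3 for drugs also frequent in minor non-chronic
conditions (e.g. proton-pump inhibitors). Exceptions implement the clinical
reassignments: benzodiazepines count toward depression/anxiety/OCD except
midazolam (N05CD08), which counts toward epilepsy; rifabutin (J04AB04)
falls under tuberculosis; lithium (N05AN01) is excluded from the
antipsychotic rule; selected immunomodulators are excluded from the
transplantation rule in favour of multiple sclerosis. A rule set in which
two patterns can claim the same code without such an exception is rejected
at load time.

The shipped mapping covers 33 candidate conditions. Its ATC lists are
best-effort reconstructions (marked `unverified` in the provenance column)
because the authoritative drug lists live in supplementary material that is
not machine-readable here; the mapping file format is the supported way to
substitute a locally validated table. A prevalence floor (default: at least
2 flagged patients) removes conditions too rare to support a coefficient,
reproducing the exclusion of conditions that are virtually absent in a
population; the mapper reports what it dropped.

## Weights and stratification

The weight transform is w = round(10·β) with half-away-from-zero rounding.
Banker's rounding would surprise epidemiologists at exact .5 boundaries;
none of the 18 shipped coefficients is affected by the choice, which the
tests assert. Negative coefficients transform fine but warn, since the
published table has none. The shipped table's stored weights are
cross-checked against the transform on every load.

Scoring is the inner product of the binary profile with the weight vector.
Conditions present in a profile but absent from the weight table contribute
zero silently — they are the conditions variable selection dropped — while
a weighted condition missing from the profile is an error, because it means
the profile was built against a different condition list.

The default stratification (≤1, 2, 3–4, 5–6, 7–9, ≥10; classes indexed 1–6
by increasing risk) is exhaustive and non-overlapping by construction;
`assign` is a branchless `searchsorted` over the class lower bounds.

## Weight derivation

Candidates are age (years, continuous), a sex indicator and the condition
flags. The selection model maximizes the Breslow-ties Cox partial
log-likelihood under an L1 penalty, path-fitted by coordinate descent
(scikit-survival's coxnet) with internal standardization of the design —
the glmnet convention; coefficients are reported on the original scale.
Breslow ties are the standard for penalized Cox paths and the natural
choice for day-resolution data; the unpenalized refit accepts
`ties="efron"` as an option. The penalty grid holds 100 log-spaced values
from the data-derived maximum down to 0.001 of it.

The cross-validation loss is the partial-likelihood deviance of Verweij &
Van Houwelingen: for fold k, d_k(λ) = −2[ℓ(β₋ₖ(λ); all) − ℓ(β₋ₖ(λ); without
fold k)], with folds stratified by event status so every training split
retains events. The one-standard-error rule picks the largest penalty whose
mean CV deviance is within one between-fold SE of the minimum. "Mean
squared error" is not a defined loss for a Cox model, so deviance — the
standard choice — is used.

Weights come by default from an **unpenalized refit** on the selected set
(statsmodels' proportional-hazards Newton fit): the magnitudes of the
published coefficients are consistent with unshrunken values, and the refit
route makes the transform independent of the penalty scale. The penalized
coefficients at the one-SE penalty are available via `refit=False`. Age and
sex may be selected and are reported, but never receive weights — the score
is a pure comorbidity measure.

Be aware that the one-SE rule is aggressively parsimonious when events are
few: around 1,000–1,500 events the CV deviance curve is nearly flat
relative to its fold-to-fold SE, and the chosen model can keep only a
handful of conditions (R's `cv.glmnet` behaves the same way on identical
data). Stable recovery of small weights needs event counts in the
several-thousands, i.e. cohorts of hundreds of thousands at ~2.4% 1-year
mortality.

## CHAID stratification

The tree is the classic ordinal chi-square automatic interaction detection
algorithm restricted to a single predictor, the integer score. At each
node the observed score values are ordinal categories; the most similar
*adjacent* pair (largest Pearson 2×2 p-value, no continuity correction,
ties broken toward the lower scores) is merged while that p-value exceeds
`alpha_merge`. The resulting g groups form the candidate split, tested with
a g×2 Pearson chi-square whose p-value is Bonferroni-multiplied by
C(c−1, g−1) — the number of ways to cut c ordinal categories into g
contiguous groups. The node splits iff the adjusted p is below
`alpha_split`, the node holds at least `min_parent` cases and every child
at least `min_child`; an undersized child vetoes the whole split (no forced
re-merge), so on small cohorts the tree may legitimately stay a single
leaf. Defaults (depth 3, parent 1000, child 500, α = 0.05) are the
parameters under which the six shipped classes were found. Expected counts
below 5 warn rather than switch to an exact test, matching classic CHAID.
The dialect (merge rule, Bonferroni convention) is one of several in
circulation, so boundaries re-derived on other data may differ legitimately.

## Validation

The c-statistic is the tie-aware Mann–Whitney probability, computed via
midranks. Confidence intervals and the paired two-score comparison use
DeLong's structural components (per-case and per-control placement
values); the paired statistic is the squared standardized AUC difference on
1 degree of freedom, so a score tested against any strictly monotone
transform of itself gives exactly 0. A percentile bootstrap CI (2,000
resamples by default) is available as an alternative. Kaplan–Meier curves
per risk class and the k-sample log-rank test are delegated to lifelines.
Comparator indices (e.g. a diagnosis-based comorbidity index) enter as
pre-computed numeric columns; computing them is out of scope. The
secondary outcome — 1-year hospitalization — reuses the identical
machinery by building survival records from the hospitalization date.

## Synthetic cohorts

The generator emulates the data-generating process the score assumes:
independent per-condition Bernoulli flags at the published cohort
prevalences (57.1% cardiovascular/cerebrovascular, 25% hyperlipidaemia,
24.8% acid-related disorders, 14.8% depression/anxiety/OCD, …); claims
drawn from each condition's own ATC patterns with per-year counts at or
just above threshold for flagged patients, and strictly below threshold for
a 5% fraction of "occasional users"; exponential survival with hazard
h_i = h₀·exp(Σβⱼxᵢⱼ) using the published coefficients as truth, h₀
calibrated by Brent root-finding so marginal 1-year mortality hits 2.4%;
administrative censoring at 365 days. Age (normal 67.5 ± 11.8 truncated at
50) and sex (56.1% female) are generated for the derivation candidate set
but carry no effect in the default truth. Exponential survival is a
deliberate simplification: only 1-year risk is identified at this horizon.

Two features of real claims data are **not** emulated, which bounds what
passing tests show. First, comorbidities are sampled independently by
default; real conditions cluster and jointly track age and frailty. A
one-factor Gaussian-copula knob (`condition_correlation`) exists for
sensitivity work but is off by default. Second, prescribing behaviour
(seasonality, switching, dose titration) is absent. A consequence of the
independence assumption worth stating plainly: the *marginal*
discrimination of the score on these synthetic cohorts is modest (AUC
≈ 0.59–0.60 even for the exact linear predictor), far below what the same
conditional coefficients yield on real, correlated populations — the
synthetic cohorts validate the pipeline's mechanics and parameter
recovery, not the score's real-world AUC.

## Numerical and interface choices

Dates are ISO-8601 only; files are comma-delimited UTF-8 with a header
(tab accepted via `sep`). Lookback and follow-up windows are half-open
[start, end); a death on the index date is invalid input because the
cohort is defined as alive at index. Malformed rows are rejected with line
numbers and reading continues unless `strict=True`. ATC codes are
uppercased and validated structurally (letter, 2 digits, letter, letter,
2 digits, or a prefix at a hierarchy level). The partial log-likelihood
uses a stable shifted log-sum-exp over the descending-time risk sets.
Fold assignment, train/test splitting and every simulator draw are pure
functions of an integer seed via `numpy.random.default_rng`.

## Problem sizes used in the test suite

Unit tests run on cohorts of 1,500–8,000 patients; the derivation recovery
check uses ten 50,000-patient cohorts; the CHAID check uses 300,000
simulated scores; discrimination and ordering checks use 100,000 patients.
These sizes keep the full suite in a few minutes while leaving the
stochastic assertions well-powered.

## Known limitations

* The shipped ATC lists are unverified reconstructions; results on real
  claims depend entirely on a locally validated mapping.
* Only reimbursed, dispensed prescriptions are modelled; private supply
  and actual consumption are invisible, as in the source databases.
* The score carries no age/sex adjustment by design; users needing
  case-mix adjustment beyond comorbidity should model those separately.
* No dose-based exposure (DDD), adherence, competing risks, time-varying
  covariates, elastic-net/ridge variants, calibration metrics or
  time-dependent ROC.
* CHAID boundaries and one-SE selections are cohort-dependent; neither is
  guaranteed to reproduce the shipped defaults on other data.
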