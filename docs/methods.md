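# Methods

This note documents the models and procedures implemented in `bzra`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real dispensing data.

## Exposure reconstruction

A dispensing record contributes its daily dose, converted to diazepam
milligram equivalents (DME), to every day of the closed interval
`[visit_date, visit_date + days_supplied − 1]`. Supplies overrunning Dec 31
of the study year are truncated at the year end. Resolution is one calendar
day; several dispensings on one day sum.

**Overlap semantics.** Overlapping prescriptions *stack*: their daily doses
add on shared days. The alternative — queueing a refill to start when the
previous supply runs out (sequential carry-forward) — would model
stockpiling explicitly, but the windowed dose maximum below already absorbs
stockpiling by averaging over three months, so stacking is the default and
keeps the daily array an exact conservation of what was dispensed
(`Σ_t d[t]` equals total dispensed DME to 1e−9 relative tolerance, enforced
by test).

## Per-patient statistics

- **Maximum averaged daily DME** — the largest mean of the daily array over
  any 90-day sliding window, with a *calendar-day* denominator (non-use days
  count as zeros). "Three months" is operationalised as 90 days; a
  use-day-denominator variant would conflate dose intensity with duration.
  Ties resolve to the earliest window.
- **Continuous-use episodes** — use-days (`d[t] > 0`) are merged into
  episodes, bridging runs separated by at most `max_gap = 3` non-use days
  (the pharmacological rationale: withdrawal symptoms emerge within ~72 h of
  cessation, so a ≤3-day interruption does not end an exposure episode).
  Episode length is the calendar span from first to last use day inclusive,
  i.e. bridged gap days count. Both the gap tolerance and the span-counting
  convention are configurable.
- **Totals and utilisation** — total yearly DME, days with any use, distinct
  (date × doctor) dispensing events, and distinct prescribers.

Both window maximum and episode detection are verified against independent
brute-force oracles (an all-windows scan; an all-pairs enumeration of use
days) on tens of thousands of random arrays.

## Classification rules

- **Overdose use**: maximum averaged daily DME strictly greater than
  40 DME/day.
- **Long-term use**: longest bridged episode **≥ 90 days**. The cutoff is
  inclusive by design: with a 30-day prescription-length ceiling, exactly
  three back-to-back refills reach 90 days and should qualify as long-term.
- **Hazardous use**: overdose AND long-term, by definition and by invariant
  (the label type rejects any other combination).
- **Over-indication use**: a patient none of whose pooled study-year ICD-10
  diagnoses prefix-matches any approved indication of any drug dispensed to
  them. Pooling across visits (rather than per-visit matching) is the
  default because diagnosis coding at any single visit is incomplete; a
  per-drug variant feeds the drug-level over-indication ranking. Patients
  with no recorded diagnosis get a missing flag and stay out of
  over-indication denominators.

All thresholds (40 DME/day, 90 days, 3-day gap, 90-day window) are recorded
in every labelling run and overridable.

## Drug registry

Conversion factors and WHO defined daily doses are configuration, not code.
The packaged table covers twelve BZRAs (eight benzodiazepines, four Z-drugs)
with factors anchored at 0.5 mg clonazepam ≡ 20 mg zolpidem ≡ 1 mg
lorazepam ≡ 10 mg diazepam and completed from the Ashton equivalence table;
DDDs follow the WHO ATC/DDD index (eszopiclone, which has no WHO DDD, uses
the customary 3 mg maintenance dose). The indication map is deliberately
*illustrative* — approved indications differ by jurisdiction and era — and
any serious use should override the `indications:` section of the registry
YAML with the local formulary. Correctness claims bind only to the anchored
conversion values.

## Synthetic cohorts

The generator emulates the structure of a multi-hospital psychiatric
out-patient dispensing database over one calendar year: patients nested in
hospitals (default five, mapped to east/east/west/central/central regions),
a female majority (63.6%), mostly ages 18–64 (76.2%), dispensings capped at
30 days' supply, and a small fraction (2%) of records with missing
gender/age/diagnosis to exercise the soft-exclusion path.

Each patient is drawn from one archetype; the default mix is 80% casual,
9% long-term stable, 4% short-term overdose, 3% hazardous, 4% doctor
shopper. Planting is **constructive**: doses and refill dates are computed
to clear, or stay clear of, the classification thresholds with margin
(e.g. hazardous patients chain 28–30-day refills with ≤3-day gaps to a span
of ≥95 days at 50–120 DME/day; casual patients are bounded so that even
fully overlapping dispensings cannot exceed a 14 DME/day window average).
The archetype therefore determines the downstream label, which makes
recovery tests sharp: a planted 3% hazardous fraction must be recovered
within binomial sampling error, and any miss indicates a pipeline defect
rather than generator noise.

Distributional forms (lognormal casual doses, uniform refill counts) are
pragmatic choices, not estimates of any real database. Consequently,
passing recovery tests shows the *pipeline* is correct, not that the
generator reproduces real-world dose/duration distributions, coding
practice, seasonal patterns or within-year care-seeking dynamics — claims
about real data require real data.

Over-indication status is planted per patient (probability 0.559 by
default): the patient's diagnoses are drawn either entirely from blocks
disjoint from every dispensed drug's indications, or to include at least one
matching code.

## Regression

The association of hazardous use with age group (reference <18), gender
(reference female), region (reference east), over-indication, visit count
and distinct-doctor count is estimated with a **linear probability model
with a hospital random intercept**, fitted by REML
(`statsmodels.MixedLM`). The identity link is the default because the
coefficients of interest are small risk differences on a rare binary
outcome, where the LPM is well behaved and directly interpretable; a
logistic variant (variational Bayes mixed GLM, log-odds scale) is provided
for sensitivity analysis, and the family is logged with every result.
Confidence intervals are Wald-type at 95%; no multiple-testing adjustment
is applied.

Numerical details: the REML profile of the random-intercept variance often
has its optimum at the boundary (variance → 0) when hospitals are
homogeneous, where a single optimizer can stall; the fit therefore runs a
deterministic optimizer cascade (BFGS → Powell → Nelder–Mead) and accepts
the first converged solution, making refits bit-identical. Covariates
constant across the cohort are dropped with a warning (rank protection);
a single-hospital design is rejected with advice to fit a fixed-effect
model. With only a handful of hospitals, region — a between-hospital
covariate — is weakly identified next to the random intercept; the model
reports it with honest (wide) intervals rather than resolving the
fragility silently.

The regression is verified by parameter recovery: a dedicated simulator
draws covariates from cohort-realistic marginals, adds a Gaussian hospital
intercept (sd 0.01), and generates the outcome from a linear-probability
mean with planted risk differences of 0.005–0.018 (the magnitude of
plausible real-world effects). At n = 20,000 and five hospitals every
planted coefficient must be recovered within two standard errors, and a
null covariate's 95% CI must cover zero in ≈95% of 500 refits
(n = 2,000 each — chosen so the calibration loop stays cheap while each fit
still estimates the variance components stably). The simulator's baseline
keeps the linear predictor inside [0, 1] for every covariate pattern, so
clipping never biases recovery.

## Descriptive statistics and tests

Medians and interquartile ranges use the linear-interpolation quartile
definition (numpy's default). Diagnosis distributions are reported over the
standard ICD-10 mental/behavioural and sleep/epilepsy blocks (F01–F09 …
F99, G40–G41, G47); a patient with diagnoses in several blocks counts in
each, so block percentages may sum above 100. Group comparisons use χ²
(Yates continuity correction on 2×2 tables, none on larger tables —
configurable), Wilcoxon rank-sum for two-group continuous comparisons, and
Kruskal–Wallis for three or more groups; both χ² and Kruskal–Wallis are
calibration-tested to hold 5% nominal type-I error within [3.5%, 6.5%] over
1,000 null simulations.

## Ingest conventions

Exclusion is two-tier. *Hard* exclusions (unknown drug, unparseable or
out-of-year date, non-positive dose or duration, missing patient ID) remove
records from all analyses and are tallied per reason. *Soft* exclusions
(missing gender, age or diagnoses) keep the patient in descriptive outputs
under an "unknown" category but drop them from the regression — mirroring
how dispensing-database studies usually handle demographic missingness.
Patients dispensed at several hospitals are assigned to the hospital of
their first dispensing for the multilevel model; dates are ISO-8601 only.

## Known limitations

- Exposure is dispensing-based: no pharmacokinetics, adherence, or actual
  ingestion; a dispensed day is an exposed day.
- The indication map defaults are illustrative, so absolute over-indication
  prevalences on real data are only meaningful with a locally curated map.
- The DME table beyond the four anchored drugs inherits the uncertainty of
  published equivalence tables; sensitivity to the factors can be probed via
  registry overrides.
- In-patient records, injections, and non-BZRA co-medication are out of
  scope; dependence diagnosis requires clinical follow-up, not claims data.
- Problem sizes in the test suite (cohorts of 10,000–20,000 patients,
  500–1,000 simulation replicates) are the package's chosen verification
  scale; all scale linearly if larger runs are wanted.
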