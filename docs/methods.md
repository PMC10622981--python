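# Methods

`pvror` implements a case/non-case disproportionality study of
neurocognitive impairment (NCI) under breast-cancer endocrine therapies
(ETs) and CDK4/6 inhibitors in a spontaneous-reporting database, together
with a synthetic report generator that makes every stage testable without
access to the real (licensed) database.

## The case/non-case design and the ROR

Within a cohort of individual case safety reports, *cases* are reports
carrying the outcome of interest and *non-cases* are all other reports.
For a drug of interest the 2×2 over reports is

|              | drug     | no drug  |
|--------------|----------|----------|
| case         | a        | c        |
| non-case     | b        | d        |

and the reporting odds ratio is ROR = ad/bc: the odds of exposure among
cases relative to non-cases. It is a reporting-disproportionality
statistic, not an incidence measure. `n_observed` is `a`;
published tables in this field often print `b` under the name "N_drug"
(the arithmetic of the tables this package emulates is only consistent
with that reading), so outputs carry `a`, `b` and `a + b` explicitly.

## Outcome definition

The outcome is resolved from a term dictionary by a query object: the
union of six group terms (dementia; mental impairment disorders;
cognitive and attention disorders and disturbances; deliria; dementia and
amnestic condition; disturbances in thinking and perception) plus explicit
PT additions, minus explicit PT exclusions, minus every PT flagged as a
neurological/psychiatric *disease* — the study counts symptoms.
Exclusions always win over inclusions. Each case-defining PT maps to
exactly one DSM-5 neurocognitive domain (social cognition, language,
executive function, complex attention, learning and memory, perceptual
motor function). Case status is report-level: one report is one case
regardless of how many matching PTs it carries, while a report with PTs
from several domains contributes to each of those domain subgroups.

Licensed dictionary content is not redistributable, so the packaged term
and drug dictionaries are small synthetic stand-ins with the real
structure (PT → HLT → HLGT → SOC, SMQ memberships, a PT → domain map;
drug → class with the nine study drugs fixed to AI/SERM/SERD/iCDK4/6).
The query ships as an editable YAML fixture.

## Cohort and attribution

The primary cohort keeps female reports dated inside the study window
(2014-01-01 through 2022-03-16, both endpoints inclusive) with known age;
drug attribution accepts all three role codes (suspect, interacting,
concomitant). Ages are banded 18–44, 45–64, 65–74, 75+ in completed
years; under-18 input is a validation error and missing age is a separate
class that never enters adjustment. Every filter's removals are recorded
in flow counts; removal counts depend on the declared filter order (and
say so), the final cohort does not.

## Estimators

* **Crude ROR** with the Woolf interval,
  exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)).  If any pooled cell is zero,
  0.5 is added to all four cells (Haldane–Anscombe) and the result is
  flagged.
* **Logistic age-adjusted ROR (primary)**: logit P(case) = β₀ +
  β₁·exposed + γ·age-class indicators (reference 45–64); aROR = exp(β₁)
  with the Wald interval. Fitted by statsmodels GLM on the aggregated
  age × exposure binomial counts, which is exactly the report-level fit
  but size-independent. Strata with no cases or no non-cases are dropped
  (they only push their own dummy to ±∞); an unidentified exposure cell,
  non-finite estimates, |β₁| > 15 or SE > 50 mark the result not
  computed with a diagnostic.
* **Mantel–Haenszel aROR (cross-check)**: Σₖ(aₖdₖ/nₖ) / Σₖ(bₖcₖ/nₖ) with
  the Robins–Breslow–Greenland variance. The test suite enforces
  agreement of the two adjusted estimators on homogeneous-OR data (≤2%)
  and the collapse of crude = MH = logistic on one stratum (10⁻⁶
  relative).

z = 1.959964 throughout, stated so interval bounds are reproducible
bit-for-bit. The published analysis says "adjusted for age" without
naming a technique and calls its intervals "credibility intervals"; both
are implemented as the standard frequentist choices above and documented
as such — no Bayesian model is described to emulate.

**Signal rules.** An ROR is calculated only when at least five case
reports carry the drug (`n_observed ≥ 5`); below that the pair is
reported as not calculable (NC), never dropped. A *signal* is a computed
pair whose lower 95% bound strictly exceeds 1. This one-sided rule has
asymptotic type-I error 2.5%, which the suite verifies by simulation
(≥1,000 null pairs). No multiplicity correction is applied across the
9 drugs × 7 outcomes × 5 analyses, matching field practice; the long
results table carries everything needed to apply one downstream.

## Sensitivity analyses

Each variant is the primary filter plus one declared modification:

* **S1** keeps all cases and restricts non-cases to reports carrying an
  oncology-class drug (antineoplastic, immunotherapy, AI/SERM/SERD, or
  CDK4/6 inhibitor — the last is itself an antineoplastic agent, and
  including it guarantees the restriction never touches a report exposed
  to a drug of interest, so only `c`/`d` can change).
* **S2** keeps healthcare-professional reports only.
* **S3**, per ET drug, re-extracts on the window from that drug's first
  report date (closed) to the first CDK4/6-inhibitor report date (open:
  the day combination reporting begins is excluded) and reruns that drug
  only. If the database has no CDK4/6-inhibitor reports the variant is
  skipped with a diagnostic.
* **S4** drops reports flagged with co-illnesses or co-treatments known
  to impair cognition; with zero flagged reports it reproduces the
  primary results row for row.

## The synthetic generator

The generator emulates the structure of a worldwide spontaneous-report
stream under the study conditions; all defaults live in
`pvror.synth` and are ordinary config fields.

* **Demographics**: age classes at (5, 29, 26, 23)% adult shares with 17%
  missing; 88% female; region mix dominated by the Americas (75%) and
  Europe (21%); 55% healthcare-professional reporters. Ages are uniform
  integers within a band (75–95 in the open band); dates uniform over the
  configured range.
* **Exposures**: per-drug Bernoulli with age-class multipliers
  (0.25, 0.5, 1, 2 from youngest to oldest) on base probabilities of
  roughly 0.5–4% per study drug, sized so relative report volumes mirror
  the study's table (palbociclib most reported, toremifene nearly
  absent). These exposure levels are far above the real database's
  per-drug shares by design: they keep the synthetic 2×2 cells
  statistically informative at feasible database sizes. Background
  (non-study) drugs are age-independent mentions; every report carries at
  least one drug. An optional coupling adds a CDK4/6 inhibitor to
  ET-exposed reports (demo default 0.15; 0 in recovery configs).
* **Outcome model**: a case arises as the union of six per-domain
  Bernoulli channels. Channel d in age class k fires with probability
  expit(logit(baseₖ·w_d) + Σⱼ ln θⱼ_d·xⱼ), where baseₖ is the age-class
  baseline (0.8–4.5%, rising with age — the built-in confounder), w_d the
  domain weight (learning and memory dominates at 0.45, mirroring the
  most-reported symptom mix), and θⱼ_d the configured conditional odds
  ratio. A domain-targeted effect multiplies only its own channel, so the
  within-stratum conditional OR for that domain outcome equals the
  configured value exactly; an NCI-level effect multiplies every channel,
  and the union ("any domain") OR equals the configured value up to a
  second-order term in the event probability (<0.5% at these rarities —
  numerically negligible against Monte-Carlo error). A domain-only effect
  therefore shows a *diluted* OR at the composite level, strictly between
  1 and the domain value, which the suite verifies by simulation.
* **Events**: each fired domain contributes one PT from that domain
  (15% chance of a second); every report adds Poisson(0.4) non-outcome
  PTs and non-cases are guaranteed at least one. The within-report PT
  count distribution is not published anywhere; this zero-truncated
  choice is a documented default, and nothing downstream depends on it
  beyond "events nonempty".
* **Seriousness** 57% among cases (30% otherwise); treatment interrupted
  for one-third of serious cases; co-illness/co-treatment flags at
  1.9%/0.7%.
* Everything is driven by one `numpy` Generator seeded from the config;
  the same config and seed give byte-identical JSONL.

Two stock configurations: `default_config()` (demo) adds pre-window dates
from 2012 and CDK4/6 launch gating (2015+) so window filtering and the S3
variant are exercised realistically, and plants the published adjusted
estimates as generating values; `recovery_config()` (parameter recovery)
uses the study window only, no launch gating and no coupling, so the
age-adjusted estimand equals the planted conditional OR exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: duplicate reports, reporting waves and secular
trends, dose/latency information, masking by competing signals beyond the
oncology co-mention flag, correlated missingness (available as a stress
knob only), and realistic per-drug exposure prevalences. Recovery tests
demonstrate statistical correctness of the pipeline under a known model,
not the validity of disproportionality analysis itself.

## Problem sizes and numerical choices

Parameter-recovery tests generate 300,000 reports per target and accept
the pipeline's aROR within 3 Monte-Carlo SEs of the generating value (SE
taken from the fitted model), while requiring the crude estimate to sit
visibly above it (the confounding displaces the crude log-OR by ≈ +0.2).
The acceptance script uses 6,000,000 reports for the primary-analysis
targets (one shared database; effects on different drugs do not
interfere because exposures are independent) and for the language-domain
target, giving Monte-Carlo SEs of ≈2% on the recovered
odds ratios; it runs in under two minutes and well under 4 GiB. Null
calibration draws 1,200 stratified tables directly from the null binomial
model (a table-level shortcut through the same estimator and rule code).

Integer percentage shares use largest-remainder rounding (shares always
sum to exactly 100, each within one point of the exact value); this
reproduces the published age-share rounding. Rendered views are pure
functions of the long results table, so re-rendering from the persisted
CSV is byte-identical.

## Known limitations

* The adjusted model conditions on age class only, exactly as the study
  describes; the demo's co-prescription coupling shows how residual
  co-medication confounding then survives (motivating S3).
* With very sparse strata the Wald interval is anticonservative; the
  ≥5-report rule keeps such pairs out of the reported set but diagnostic
  crude estimates may still carry the Haldane correction flag.
* The S1 comparator change is faithful to its definition, but in the
  synthetic database cases are drawn from all reports rather than from an
  oncology population, so S1 shifts estimates downward much more than it
  would in the emulated study population (see `examples/05_sensitivity.py`).
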