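# pvror

Case/non-case disproportionality analysis for spontaneous adverse-event
reporting databases, built around one concrete study design: age-adjusted
reporting odds ratios (RORs) for neurocognitive impairment (NCI) under
breast-cancer endocrine therapies (anastrozole, letrozole, exemestane,
tamoxifen, toremifene, fulvestrant) and CDK4/6 inhibitors (palbociclib,
ribociclib, abemaciclib), with DSM-5 domain subgroups and four sensitivity
analyses. It is written for pharmacovigilance and pharmacoepidemiology
analysts who want the whole pipeline — case definition, cohort
restriction, estimation, signal rules, rendered tables — as tested,
reusable code rather than a one-off script.

Real pharmacovigilance databases (and the licensed MedDRA/WHODrug
dictionaries they use) are access-restricted, so the package ships a
synthetic report generator with known ground truth: every stage can be
exercised, and the estimators validated by parameter recovery, without
any data access.

## The statistic

Within a filtered cohort of reports, cases are reports carrying the
outcome and non-cases are all other reports. For drug *j*,

```
ROR = (a·d) / (b·c)
```

where `a`/`b` are case/non-case reports mentioning the drug and `c`/`d`
those not mentioning it. The age-adjusted ROR (aROR) is estimated by
logistic regression,

```
logit P(case) = β₀ + β₁·exposed + γ·age-class,   aROR = exp(β₁),
```

with a Mantel–Haenszel estimator (Robins–Breslow–Greenland variance) as
an independent cross-check. Intervals are 95% Wald/Woolf on the log
scale. A drug–event pair is a *signal* when its lower 95% bound strictly
exceeds 1 and at least five case reports carry the drug; below five the
ROR is reported as not calculable (NC).

## Worked example

`examples/03_crude_vs_adjusted.py` generates 300,000 synthetic reports in
which the generating conditional odds ratio for palbociclib is exactly 1,
but older reports have both more drug exposure and more neurocognitive
events (age confounding). It prints:

```
stratified 2x2 (age class: a, b, c, d):
  18-44  (0, 169, 129, 14613)
  45-64  (28, 1585, 1236, 84083)
  65-74  (85, 3046, 1810, 72604)
  75+    (276, 5310, 2810, 60996)
crude              ROR = 1.422 (95% CI 1.287-1.570)
mantel_haenszel    ROR = 1.126 (95% CI 1.013-1.252)
logistic_adjusted  ROR = 1.126 (95% CI 1.013-1.252)
```

The crude ROR (1.42) would look like a clear signal, but it is pure age
confounding: within every age stratum the association is null, and both
adjusted estimators recover that. This is why the study design adjusts
for age. The other examples walk through generation
(`01_generate_reports.py`), the symptom-level case definition and DSM-5
domain labels (`02_define_cases.py`), the full study with rendered tables
and flow counts (`04_full_study.py`), and the four sensitivity variants
(`05_sensitivity.py`).

A thin CLI wraps the same pipeline:

```
pvror generate -n 50000 --seed 1 -o reports.jsonl
pvror analyze -r reports.jsonl -o study_output/
```

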