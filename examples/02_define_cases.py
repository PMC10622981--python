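"""Resolve the neurocognitive-impairment case definition and label reports.

The outcome is defined as a query over the term dictionary: six group
terms covering cognition, attention, memory, deliria and thought
disturbances, minus every term flagged as a neurological/psychiatric
disease (the study counts symptoms, not diagnoses).  A report is one case
no matter how many matching terms it carries.
"""

from pvror import (
    default_config,
    generate_reports,
    label_reports,
    load_default_case_query,
    load_default_term_dictionary,
    resolve_query,
)
from pvror.casedef import DOMAIN_COLUMNS

term_dict = load_default_term_dictionary()
query = load_default_case_query()
case_set = resolve_query(query, term_dict)

print(f"case-defining preferred terms: {len(case_set)}")
print(f"disease terms excluded       : {len(term_dict.disease_pts)}")

reports = generate_reports(default_config(n_reports=20_000, seed=7))
labels = label_reports(reports, case_set, term_dict.domain_map)

n_cases = int(labels["is_case"].sum())
print(f"\ncases among {reports.n_reports} reports: {n_cases} "
      f"({100 * n_cases / reports.n_reports:.1f}%)")

print("\ncases contributing to each DSM-5 domain subgroup:")
for domain, col in DOMAIN_COLUMNS.items():
    print(f"  {domain:25s} {int(labels[col].sum()):5d}")

print(
    "\nA report with terms from two domains counts once at the composite "
    "level but contributes to both domain subgroup analyses."
)
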