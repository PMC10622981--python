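"""Why the study adjusts for age: crude vs adjusted ROR under confounding.

Here the generating conditional odds ratio is exactly 1 (no real
association), but older reports carry both more exposure and more
neurocognitive events.  The crude reporting odds ratio is pushed above 1
by that confounding; the Mantel-Haenszel and logistic age-adjusted
estimates recover the null.
"""

from pvror import (
    generate_reports,
    label_reports,
    load_default_drug_dictionary,
    load_default_term_dictionary,
    load_default_case_query,
    resolve_query,
    build_table,
    crude_ror,
    mh_adjusted_ror,
)
from pvror.disprop import lr_from_table
from pvror.synth import recovery_config

term_dict = load_default_term_dictionary()
drug_dict = load_default_drug_dictionary()

config = recovery_config(effects=(), n_reports=300_000, seed=11)  # all ORs = 1
reports = generate_reports(config, term_dict, drug_dict)
case_set = resolve_query(load_default_case_query(), term_dict)
labels = label_reports(reports, case_set, term_dict.domain_map)

table = build_table(reports, "D07", labels)  # palbociclib
print("stratified 2x2 (age class: a, b, c, d):")
for k, cells in table.adult_strata().items():
    print(f"  {k.value:6s} {cells}")

for res in (crude_ror(table), mh_adjusted_ror(table), lr_from_table(table)):
    print(
        f"{res.method:18s} ROR = {res.point:.3f} "
        f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})"
    )

print(
    "\nThe generating odds ratio is 1.0: the crude estimate is biased "
    "upward by age confounding while both adjusted estimators sit on the "
    "null, which is why the primary analysis reports age-adjusted RORs."
)
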