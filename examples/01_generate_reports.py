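"""Generate a small synthetic spontaneous-report database and look inside.

The generator emulates a worldwide pharmacovigilance database restricted
to the study conditions: mostly female reports, the study's adult age mix
with 17% missing age, multi-drug multi-event reports, and built-in age
confounding (older reports carry both more drug exposure and more
neurocognitive events).
"""

from pvror import default_config, generate_reports

config = default_config(n_reports=20_000, seed=42)
reports = generate_reports(config)
reports.validate()

print(f"reports generated : {reports.n_reports}")
print(f"drug mentions     : {len(reports.drug_mentions)}")
print(f"event terms       : {len(reports.events)}")

shares = reports.reports["age_class"].value_counts(normalize=True)
print("\nage mix (fraction of reports):")
for k, v in shares.sort_index().items():
    print(f"  {k:8s} {v:.3f}")

print("\nfirst two reports as JSON-ready records:")
for i, rep in enumerate(reports.iter_reports()):
    print(" ", rep.to_json_obj())
    if i == 1:
        break

print(
    "\nEach line is one individual case safety report: demographics, dated "
    "drug mentions with reporter-assigned roles, and coded event terms."
)
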