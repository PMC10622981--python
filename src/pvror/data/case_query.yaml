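# Study case definition: neurocognitive-impairment symptom terms.
# Groups are resolved against the term dictionary (HLGT or SMQ names);
# disease-flagged PTs are always removed, and explicit exclusions win
# over inclusions.
included_groups:
  - dementia
  - mental impairment disorders
  - cognitive and attention disorders and disturbances
  - deliria
  - dementia and amnestic condition
  - disturbances in thinking and perception
included_pts: []
excluded_pts: []
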