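"""Map samples to regions: father's birthplace first, then own.

Samples without any birthplace, born abroad, or from the excluded island
region are removed; the ledger accounts for every input sample.
"""

import ylandscape as yl

demo = yl.DemographyConfig.default(n_samples=600, seed=42)
tree = yl.simulate_tree(demo, depth=2, branching=2)
cohort = yl.simulate_cohort(tree, demo, yl.NoiseConfig())

assignments, ledger = yl.assign_regions(cohort.metadata)
print(ledger)
print("retained + exclusions == input:",
      ledger["retained"] + ledger["missing_geo"] + ledger["foreign"]
      + ledger["excluded_region"] == ledger["input"])
print(assignments.head().to_string(index=False))
# provenance 'father' means the father's birth region was used, pushing the
# geographic snapshot one generation back in time.
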