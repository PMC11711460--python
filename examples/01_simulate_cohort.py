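"""Generate a synthetic Y-chromosome cohort and look at its structure.

Draws 600 men over 19 regions with eastern oversampling from a known
haplogroup genealogy, with QC-failing decoy variants and corrupted
metadata, and prints the cohort's composition.
"""

import ylandscape as yl

demo = yl.DemographyConfig.default(n_samples=600, seed=42)
tree = yl.simulate_tree(demo, depth=3, branching=2)
cohort = yl.simulate_cohort(tree, demo, yl.NoiseConfig())

print(f"leaf haplogroups: {tree.leaves}")
print(f"strong-cline leaves (east, west): {tree.gradient_leaves}")
print(f"variants emitted: {cohort.gm.n_variants} "
      f"({(cohort.gm.variants.truth_class.str.startswith('clean')).sum()} clean)")
print(f"samples: {cohort.gm.n_samples}")
print("true haplogroup counts:")
print(cohort.truth_samples["true_haplogroup"].value_counts().to_string())
# The clean variants are the genealogy's defining markers plus private
# mutations; the rest are decoys built to fail one QC rule each.
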