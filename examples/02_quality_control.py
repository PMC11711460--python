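"""Run the variant/sample QC cascade and read the exclusion ledger.

Heterozygous calls in the haploid data are masked first; variants are then
removed for non-PASS filter, mappability-mask overlap, non-SNP or
monomorphic state, low call rate, low depth, strand bias FS > 13 or mapping
quality < 50, and finally samples with > 75% missingness are dropped.
"""

import ylandscape as yl

demo = yl.DemographyConfig.default(n_samples=600, seed=42)
tree = yl.simulate_tree(demo, depth=3, branching=2)
cohort = yl.simulate_cohort(tree, demo, yl.NoiseConfig())

gm, ledger = yl.apply_qc(cohort.gm, cohort.mask)
for field in ("input_variants", "het_set_missing", "nonpass_removed",
              "mask_removed", "nonpolymorphic_removed", "low_gt_removed",
              "low_dp_removed", "high_fs_removed", "low_mq_removed",
              "surviving_variants", "samples_removed", "surviving_samples"):
    print(f"{field:24s} {getattr(ledger, field)}")
print("ledger additive:", ledger.check_additive())

# The reference-concordance convenience: fraction of surviving variants
# found in external reference data, as a percentage.
print("concordance(14235/15012) =",
      round(yl.concordance_fraction(14235, 15012)), "%")
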