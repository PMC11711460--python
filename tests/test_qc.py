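"""QC cascade: stage attribution, idempotence, order-invariance oracle."""

import numpy as np
import pandas as pd
import pytest

import ylandscape as yl
from ylandscape.matrix import GenotypeMatrix, HET, MISSING

from helpers import make_matrix


def _empty_matrix():
    variants = pd.DataFrame(
        columns=["pos", "ref", "alt", "filter", "dp_mean", "fs", "mq"]
    ).astype({"pos": int})
    return GenotypeMatrix(variants, np.empty((0, 3), dtype=np.int8),
                         ["s1", "s2", "s3"])


def test_empty_vcf_gives_zero_ledger():
    gm, ledger = yl.apply_qc(_empty_matrix())
    assert gm.n_variants == 0
    assert ledger.input_variants == ledger.surviving_variants == 0
    assert ledger.check_additive()


def test_crafted_twelve_variant_fixture():
    """One violation of each rule plus 5 clean sites: 5 survive and every
    removal stage accounts for exactly one variant (the non-SNP site counts
    under the monomorphic/SNP stage)."""
    n = 20
    base = [1] * 6 + [0] * (n - 6)
    G = np.array([base] * 12, dtype=np.int8)
    gm = make_matrix(G, positions=list(range(100, 220, 10)))
    v = gm.variants
    ids = list(v.index)
    v.loc[ids[5], "filter"] = "FAIL_QUAL"   # -> nonpass
    mask = [(159, 160)]                     # pos 160 = ids[6] -> mask
    v.loc[ids[7], "alt"] = "GT"             # non-SNP -> nonpolymorphic
    gm.G[8, :2] = MISSING                   # call rate 18/20 -> low_gt
    v.loc[ids[9], "dp_mean"] = 5.0          # -> low_dp
    v.loc[ids[10], "fs"] = 14.0             # -> high_fs
    v.loc[ids[11], "mq"] = 45.0             # -> low_mq
    out, ledger = yl.apply_qc(gm, mask)
    assert ledger.surviving_variants == 5
    assert set(out.variants.index) == set(ids[:5])
    for stage in ("nonpass", "mask", "nonpolymorphic", "low_gt", "low_dp",
                  "high_fs", "low_mq"):
        assert getattr(ledger, f"{stage}_removed") == 1, stage
    assert ledger.check_additive()
    assert ledger.removal_stage[ids[10]] == "high_fs"


def test_het_calls_masked_before_site_statistics():
    n = 20
    base = [1] * 6 + [0] * (n - 6)
    G = np.array([base, base], dtype=np.int8)
    G[1, :2] = HET  # het-masking drops the call rate to 18/20 < 0.95
    gm = make_matrix(G)
    out, ledger = yl.apply_qc(gm)
    assert ledger.het_set_missing == 2
    assert ledger.low_gt_removed == 1
    assert out.n_variants == 1
    assert (out.G != HET).all()


def test_mask_validation():
    gm = make_matrix(np.array([[1, 0, 0, 1]], dtype=np.int8))
    with pytest.raises(ValueError):
        yl.apply_qc(gm, mask=[(10, 10)])


def test_idempotence(noisy_cohort):
    gm1, _ = yl.apply_qc(noisy_cohort.gm, noisy_cohort.mask)
    gm2, ledger2 = yl.apply_qc(gm1, noisy_cohort.mask)
    assert list(gm2.variants.index) == list(gm1.variants.index)
    assert gm2.samples == gm1.samples
    assert ledger2.surviving_variants == ledger2.input_variants
    np.testing.assert_array_equal(gm1.G, gm2.G)


@pytest.mark.parametrize("loosened", [
    dict(min_gt_rate=0.80), dict(min_mean_depth=5.0), dict(max_fs=30.0),
    dict(min_mq=30.0), dict(max_sample_missing=0.95),
])
def test_loosening_thresholds_is_monotone(noisy_cohort, loosened):
    _, strict = yl.apply_qc(noisy_cohort.gm, noisy_cohort.mask)
    _, loose = yl.apply_qc(noisy_cohort.gm, noisy_cohort.mask,
                           yl.QCThresholds(**loosened))
    assert loose.surviving_variants >= strict.surviving_variants


def test_decoys_removed_at_intended_stage_and_clean_kept():
    """With genotype-level noise off, every decoy is removed at the stage it
    was built to violate and no clean variant is removed."""
    demo = yl.DemographyConfig.default(n_samples=400, seed=21)
    tree = yl.simulate_tree(demo, depth=2, branching=2)
    noise = yl.NoiseConfig(missing_rate=0.0, het_artifact_rate=0.0,
                           n_high_missing_samples=0)
    cohort = yl.simulate_cohort(tree, demo, noise)
    out, ledger = yl.apply_qc(cohort.gm, cohort.mask)
    truth_class = cohort.gm.variants["truth_class"]
    intended = {"decoy_nonpass": "nonpass", "decoy_mask": "mask",
                "monomorphic": "nonpolymorphic", "decoy_lowcall": "low_gt",
                "decoy_dp": "low_dp", "decoy_fs": "high_fs",
                "decoy_mq": "low_mq"}
    for vid, cls in truth_class.items():
        if cls in intended:
            assert ledger.removal_stage.get(vid) == intended[cls], vid
    clean = truth_class[truth_class.str.startswith("clean")].index
    assert set(clean) <= set(out.variants.index)


def test_surviving_set_is_order_invariant(noisy_cohort):
    """The cascade's fixed order affects ledger attribution only: the
    surviving set equals the order-free conjunction of all rules, iterated
    with sample removal to a fixed point."""
    th = yl.QCThresholds()
    out, _ = yl.apply_qc(noisy_cohort.gm, noisy_cohort.mask)

    gm = noisy_cohort.gm
    G = gm.G.copy()
    G[G == HET] = MISSING
    v = gm.variants
    keep_s = np.ones(len(gm.samples), dtype=bool)
    while True:
        sub = G[:, keep_s]
        is_snp = (v["ref"].str.len() == 1) & (v["alt"].str.len() == 1)
        poly = ((sub == 1).sum(1) > 0) & ((sub == 0).sum(1) > 0)
        in_mask = np.zeros(len(v), dtype=bool)
        for a, b in noisy_cohort.mask:
            in_mask |= (v["pos"].to_numpy() > a) & (v["pos"].to_numpy() <= b)
        ok = ((v["filter"] == "PASS").to_numpy() & ~in_mask
              & is_snp.to_numpy() & poly
              & ((sub != MISSING).mean(1) >= th.min_gt_rate)
              & (v["dp_mean"].to_numpy() >= th.min_mean_depth)
              & (v["fs"].to_numpy() <= th.max_fs)
              & (v["mq"].to_numpy() >= th.min_mq))
        new_keep = keep_s & ((G[ok] == MISSING).mean(0) <= th.max_sample_missing)
        if (new_keep == keep_s).all():
            break
        keep_s = new_keep
    assert set(v.index[ok]) == set(out.variants.index)
    assert [s for s, k in zip(gm.samples, keep_s) if k] == out.samples


def test_concordance_fraction_examples():
    assert round(yl.concordance_fraction(14235, 15012)) == 95
    assert yl.concordance_fraction(14235, 15012) == pytest.approx(94.8248, abs=1e-3)
    assert yl.concordance_fraction(0, 10) == 0.0
    assert yl.concordance_fraction(7, 8) == 87.5
    with pytest.raises(ValueError):
        yl.concordance_fraction(1, 0)
    with pytest.raises(ValueError):
        yl.concordance_fraction(5, 4)


def test_vcf_bed_round_trip(tmp_path, noisy_cohort):
    """QC on the written VCF+BED equals QC on the in-memory matrix."""
    vcf = tmp_path / "cohort.vcf"
    bed = tmp_path / "mask.bed"
    noisy_cohort.write_vcf(vcf)
    noisy_cohort.write_mask(bed)
    gm_disk, led_disk = yl.apply_qc_vcf(vcf, bed)
    gm_mem, led_mem = yl.apply_qc(noisy_cohort.gm, noisy_cohort.mask)
    assert list(gm_disk.variants.index) == list(gm_mem.variants.index)
    assert gm_disk.samples == gm_mem.samples
    np.testing.assert_array_equal(gm_disk.G, gm_mem.G)
    assert led_disk.surviving_variants == led_mem.surviving_variants


def test_vcf_without_gt_rejected(tmp_path):
    p = tmp_path / "bad.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chrY>\n"
        "##FORMAT=<ID=DP,Number=1,Type=Integer,Description=\"Depth\">\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "chrY\t100\tv1\tA\tG\t.\tPASS\t.\tDP\t10\n"
    )
    with pytest.raises(ValueError):
        yl.read_vcf(p)
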