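"""Variant- and sample-level quality control for a haploid Y VCF.

The cascade mirrors standard short-read Y-chromosome QC: heterozygous calls
in the haploid data are treated as artifacts and set missing before any site
statistic is computed; variants are then removed, in a fixed order, for
failing the upstream caller's FILTER, overlapping the mappability exclusion
mask, being non-SNP or monomorphic, low call rate, low mean depth, high
strand bias (FS) or low mapping quality; finally samples with excessive
missingness are dropped.  The variant/sample filters are iterated to a fixed
point so the operation is idempotent (removing a sample can in principle
render a variant monomorphic).  The fixed order determines only how the
ledger attributes removals, not which variants survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import GenotypeMatrix, HET, MISSING
from .vcfio import read_bed, read_vcf

__all__ = ["QCThresholds", "QCLedger", "apply_qc", "apply_qc_vcf",
           "concordance_fraction"]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds.

    ``min_gt_rate`` is the per-site successful-call rate across samples
    (the "genotyping quality >= 95%" rule read as a site call-rate
    property); the remainder are the conventional INFO-field cutoffs.
    """

    min_gt_rate: float = 0.95
    min_mean_depth: float = 10.0
    max_fs: float = 13.0
    min_mq: float = 50.0
    max_sample_missing: float = 0.75

    def __post_init__(self):
        for name in ("min_gt_rate", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("min_mean_depth", "max_fs", "min_mq"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class QCLedger:
    """Additive accounting of the cascade: ``input_variants`` equals
    ``surviving_variants`` plus the sum of the per-stage removals."""

    input_variants: int = 0
    het_set_missing: int = 0  # genotype calls masked, not a variant stage
    nonpass_removed: int = 0
    mask_removed: int = 0
    nonpolymorphic_removed: int = 0
    low_gt_removed: int = 0
    low_dp_removed: int = 0
    high_fs_removed: int = 0
    low_mq_removed: int = 0
    surviving_variants: int = 0
    input_samples: int = 0
    samples_removed: int = 0
    surviving_samples: int = 0
    removal_stage: dict = field(default_factory=dict)  # variant id -> stage

    def check_additive(self) -> bool:
        return self.input_variants == self.surviving_variants + (
            self.nonpass_removed + self.mask_removed
            + self.nonpolymorphic_removed + self.low_gt_removed
            + self.low_dp_removed + self.high_fs_removed + self.low_mq_removed
        )


def _in_mask(pos: np.ndarray, intervals) -> np.ndarray:
    """pos is 1-based; intervals are 0-based half-open."""
    hit = np.zeros(len(pos), dtype=bool)
    for start, end in intervals:
        hit |= (pos > start) & (pos <= end)
    return hit


def apply_qc(
    gm: GenotypeMatrix,
    mask=(),
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, QCLedger]:
    """Run the full cascade; returns the filtered matrix and the ledger.

    ``mask`` is an iterable of 0-based half-open (start, end) intervals or a
    path to a BED file.
    """
    th = thresholds or QCThresholds()
    if isinstance(mask, (str, bytes)) or hasattr(mask, "read_text"):
        mask = read_bed(mask)
    else:
        mask = list(mask)
        for start, end in mask:
            if end <= start:
                raise ValueError(f"mask interval with end <= start: {(start, end)}")

    ledger = QCLedger(input_variants=gm.n_variants, input_samples=gm.n_samples)

    G = gm.G.copy()
    ledger.het_set_missing = int((G == HET).sum())
    G[G == HET] = MISSING
    gm = GenotypeMatrix(gm.variants.copy(), G, list(gm.samples))

    stage_counts = {
        "nonpass": 0, "mask": 0, "nonpolymorphic": 0, "low_gt": 0,
        "low_dp": 0, "high_fs": 0, "low_mq": 0,
    }

    changed = True
    while changed:
        changed = False
        v = gm.variants
        G = gm.G
        n_var = gm.n_variants
        alive = np.ones(n_var, dtype=bool)

        def drop(mask_bool, stage):
            nonlocal alive, changed
            hit = alive & mask_bool
            stage_counts[stage] += int(hit.sum())
            for vid in v.index[hit]:
                ledger.removal_stage[vid] = stage
            if hit.any():
                changed = True
            alive &= ~mask_bool

        if n_var:
            filt = v["filter"].fillna("PASS").to_numpy()
            drop(filt != "PASS", "nonpass")
            drop(_in_mask(v["pos"].to_numpy(), mask), "mask")

            ref = v["ref"].astype(str).to_numpy()
            alt = v["alt"].astype(str).to_numpy()
            is_snp = (np.char.str_len(ref.astype(str)) == 1) & (
                np.char.str_len(alt.astype(str)) == 1) & (alt != ".")
            if "n_alt" in v.columns:
                is_snp &= v["n_alt"].fillna(1).to_numpy() <= 1
            n_derived = (G == 1).sum(axis=1)
            n_ancestral = (G == 0).sum(axis=1)
            polymorphic = (n_derived > 0) & (n_ancestral > 0)
            drop(~(is_snp & polymorphic), "nonpolymorphic")

            call_rate = (G != MISSING).mean(axis=1) if gm.n_samples else np.zeros(n_var)
            drop(call_rate < th.min_gt_rate, "low_gt")
            drop(v["dp_mean"].to_numpy() < th.min_mean_depth, "low_dp")
            drop(v["fs"].to_numpy() > th.max_fs, "high_fs")
            drop(v["mq"].to_numpy() < th.min_mq, "low_mq")

        gm = gm.subset_variants(alive)

        # sample-wise missingness over surviving variants
        if gm.n_variants and gm.n_samples:
            miss = (gm.G == MISSING).mean(axis=0)
            keep = miss <= th.max_sample_missing
            if not keep.all():
                changed = True
                ledger.samples_removed += int((~keep).sum())
                gm = gm.subset_samples(keep)

    ledger.nonpass_removed = stage_counts["nonpass"]
    ledger.mask_removed = stage_counts["mask"]
    ledger.nonpolymorphic_removed = stage_counts["nonpolymorphic"]
    ledger.low_gt_removed = stage_counts["low_gt"]
    ledger.low_dp_removed = stage_counts["low_dp"]
    ledger.high_fs_removed = stage_counts["high_fs"]
    ledger.low_mq_removed = stage_counts["low_mq"]
    ledger.surviving_variants = gm.n_variants
    ledger.surviving_samples = gm.n_samples
    return gm, ledger


def apply_qc_vcf(vcf_path, bed_path=None, thresholds: QCThresholds | None = None):
    """Convenience wrapper: read VCF (and optional BED mask) from disk."""
    gm = read_vcf(vcf_path)
    mask = read_bed(bed_path) if bed_path else ()
    return apply_qc(gm, mask, thresholds)


def concordance_fraction(n_found: int, n_total: int) -> float:
    """Percentage of variants found in reference data: 100 * n_found/n_total.

    Use ``round()`` on the result for the integer convenience form.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_found <= n_total:
        raise ValueError("need 0 <= n_found <= n_total")
    return 100.0 * n_found / n_total
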