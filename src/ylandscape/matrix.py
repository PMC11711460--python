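"""Genotype matrix container shared across the pipeline.

Genotypes are haploid and binary: 0 ancestral (REF), 1 derived (ALT),
-1 missing.  Pre-QC matrices may additionally hold 2 for heterozygous
artifact calls (diploid "0/1" records in an otherwise haploid VCF); QC
converts these to missing before any site statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1
HET = 2

__all__ = ["GenotypeMatrix", "MISSING", "HET"]


@dataclass
class GenotypeMatrix:
    """A variants x samples haploid genotype matrix with site annotations.

    ``variants`` is indexed by variant id and carries at least ``pos``
    (1-based); QC additionally expects ``ref``, ``alt``, ``filter``,
    ``dp_mean``, ``fs``, ``mq`` where available.
    """

    variants: pd.DataFrame
    G: np.ndarray  # int8, shape (n_variants, n_samples)
    samples: list[str]

    def __post_init__(self):
        if self.G.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"G shape {self.G.shape} inconsistent with "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            lookup = {v: i for i, v in enumerate(self.variants.index)}
            idx = np.array([lookup[v] for v in mask_or_ids], dtype=int)
        return GenotypeMatrix(self.variants.iloc[idx], self.G[idx], self.samples)

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        """keep: boolean mask or list of sample ids."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            self.variants, self.G[:, idx], [self.samples[i] for i in idx]
        )

    def derived_counts(self) -> np.ndarray:
        """Per-variant derived-allele count among non-missing calls."""
        return (self.G == 1).sum(axis=1)

    def call_rates(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls (het counts as a call
        only if still encoded; QC masks hets before using this)."""
        return (self.G != MISSING).mean(axis=1)

    def carriers(self, variant_id) -> set[str]:
        i = self.variants.index.get_loc(variant_id)
        return {self.samples[j] for j in np.flatnonzero(self.G[i] == 1)}
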