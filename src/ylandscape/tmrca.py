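"""Rho-statistic TMRCA estimation for haplogroup clades.

The rho statistic is the mean number of derived mutations per sampled
lineage accumulated since the clade's most recent common ancestor; a
years-per-mutation calibration constant converts it to a time.  Mutations
counted are the QC-passing variants (any carrier count) whose carriers all
lie within the clade — i.e. mutations younger than the clade MRCA — with
the clade's own defining markers excluded since those predate the MRCA.
Shared sub-clade mutations count once per tip that carries them (the
standard rho convention).

Two uncertainty modes are provided: ``poisson_star`` treats the genealogy
as a star (sigma = sqrt(rho / n)); ``saillard`` weights each mutation by
the fraction of tips it subtends (sigma^2 = sum_v (k_v / n)^2, the
tree-weighted recursion expressed per variant), which requires the
per-variant within-clade carrier counts that :func:`count_derived` returns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .tree import CladeTree, ROOT

__all__ = ["RhoEstimate", "count_derived", "rho_tmrca"]


@dataclass
class RhoEstimate:
    clade: str
    n: int
    rho: float
    sigma_rho: float
    tmrca_years: float
    ci_low: float
    ci_high: float
    calibration: float
    sigma_mode: str


def count_derived(
    gm: GenotypeMatrix, tree: CladeTree, clade: str
) -> tuple[pd.Series, pd.Series]:
    """Per-tip derived-mutation counts m_i for a clade.

    ``gm`` should be the QC-passing matrix before any MAC filter, so private
    (singleton) mutations are counted.  Returns (m, k): ``m`` indexed by
    member sample, ``k`` the within-clade carrier count of each counted
    variant (input for the ``saillard`` sigma mode).
    """
    if clade not in tree.clades or clade == ROOT:
        raise ValueError(f"{clade!r} is not a clade in the tree")
    members = tree.clades[clade].members
    if len(members) < 2:
        raise ValueError(f"clade {clade} has fewer than 2 members")
    defining = set(tree.clades[clade].markers)

    member_idx = np.array([i for i, s in enumerate(gm.samples) if s in members])
    inside = np.zeros(gm.n_samples, dtype=bool)
    inside[member_idx] = True

    D = gm.G == 1
    n_in = D[:, inside].sum(axis=1)
    n_out = D[:, ~inside].sum(axis=1)
    own = gm.variants.index.isin(defining)
    counted = (n_in > 0) & (n_out == 0) & ~own

    sub = D[np.ix_(counted, member_idx)]
    m = pd.Series(sub.sum(axis=0), index=[gm.samples[i] for i in member_idx],
                  name="m")
    k = pd.Series(n_in[counted], index=gm.variants.index[counted], name="k")
    return m, k


def rho_tmrca(
    m,
    calibration: float,
    sigma_mode: str = "poisson_star",
    carriers_per_variant=None,
    clade: str = "",
    z: float = 1.96,
) -> RhoEstimate:
    """Rho estimate and CI from per-tip mutation counts.

    ``calibration`` is the years-per-mutation constant for the callable
    region (e.g. 1 / (rate_per_bp_per_year * callable_bp)).  The CI is
    rho +/- z * sigma, scaled by the calibration and truncated below at 0.
    ``sigma_mode="saillard"`` requires ``carriers_per_variant`` (the k
    vector from :func:`count_derived`).
    """
    m = np.asarray(m, dtype=float)
    n = len(m)
    if n < 2:
        raise ValueError("need at least 2 tips")
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    rho = float(m.mean())
    if sigma_mode == "poisson_star":
        sigma = float(np.sqrt(rho / n))
    elif sigma_mode == "saillard":
        if carriers_per_variant is None:
            raise ValueError("saillard mode needs carriers_per_variant")
        k = np.asarray(carriers_per_variant, dtype=float)
        sigma = float(np.sqrt(((k / n) ** 2).sum()))
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    lo = max(0.0, rho - z * sigma)
    hi = rho + z * sigma
    return RhoEstimate(
        clade=clade, n=n, rho=rho, sigma_rho=sigma,
        tmrca_years=rho * calibration,
        ci_low=lo * calibration, ci_high=hi * calibration,
        calibration=calibration, sigma_mode=sigma_mode,
    )
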