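"""Autosomal structure alongside the Y: PCA, PC-frequency correlation,
carrier rank tests and Hudson F_ST with block-jackknife standard errors.

These are the cross-checks relating patrilineal haplogroups to genome-wide
ancestry: regional mean PC scores correlated with regional haplogroup
frequencies, Mann-Whitney comparisons of PC scores between carrier groups
within a region, and pairwise Hudson F_ST between population samples
combined as a ratio of averages over loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PCScores", "FstResult", "pca", "pc_frequency_correlation",
           "carrier_rank_test", "hudson_fst", "hudson_components"]


@dataclass
class PCScores:
    scores: pd.DataFrame      # samples x components, zero-mean columns
    eigenvalues: np.ndarray   # non-increasing
    loci_used: list


@dataclass
class FstResult:
    pair: tuple
    fst: float
    se: float
    n_loci: int
    block_size: int
    degenerate: bool = False


def pca(dosages: pd.DataFrame, n_components: int = 20) -> PCScores:
    """PCA of column-standardised dosages via SVD.

    Missing dosages are mean-imputed per locus and zero-variance loci
    dropped.  Deterministic sign convention: each component's
    largest-magnitude loading is positive.
    """
    if len(dosages) < 2:
        raise ValueError("need at least 2 samples")
    X = dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    loci_used = list(dosages.columns[keep])
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    k = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention on the loadings
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = pd.DataFrame(
        U * S, index=dosages.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    eigenvalues = S ** 2 / (X.shape[0] - 1)
    return PCScores(scores=scores, eigenvalues=eigenvalues, loci_used=loci_used)


def pc_frequency_correlation(
    pcs: PCScores,
    sample_regions: pd.Series,
    region_freq: pd.Series,
    component: int = 1,
) -> tuple[float, float, bool]:
    """Pearson correlation, across regions, of the regional mean PC score
    with the regional haplogroup frequency.

    ``sample_regions`` maps sample id -> region; ``region_freq`` gives the
    haplogroup's frequency per region.  Returns (r, p, degenerate); a
    zero-variance input is degenerate and reported as r = 0, p = 1.
    """
    col = f"PC{component}"
    mean_pc = pcs.scores[col].groupby(sample_regions.reindex(pcs.scores.index)).mean()
    common = [r for r in region_freq.index if r in mean_pc.index]
    if len(common) < 3:
        raise ValueError("need at least 3 regions")
    x = mean_pc[common].to_numpy()
    y = region_freq[common].to_numpy(dtype=float)
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return 0.0, 1.0, True
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), False


def carrier_rank_test(
    pcs: PCScores, group_a, group_b, component: int = 1
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing a PC between carrier groups
    (normal approximation with tie correction; exact for tiny groups)."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    col = f"PC{component}"
    a = pcs.scores.loc[group_a, col].to_numpy()
    b = pcs.scores.loc[group_b, col].to_numpy()
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def hudson_components(ac1, n1, ac2, n2):
    """Per-locus Hudson numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)
    with p the sample allele frequency and n the chromosome count.
    """
    ac1 = np.asarray(ac1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 chromosomes per population")
    p1, p2 = ac1 / n1, ac2 / n2
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(
    ac1, n1, ac2, n2, block_size: int = 500, pair: tuple = ("pop1", "pop2")
) -> FstResult:
    """Multi-locus Hudson F_ST as a ratio of averages, with a block
    jackknife over contiguous locus blocks for the standard error.

    Monomorphic-everywhere input has a zero denominator sum and is returned
    flagged ``degenerate`` with NaN estimates.
    """
    num, den = hudson_components(ac1, n1, ac2, n2)
    n_loci = len(num)
    if den.sum() == 0:
        return FstResult(pair=pair, fst=float("nan"), se=float("nan"),
                         n_loci=n_loci, block_size=block_size, degenerate=True)
    fst = float(num.sum() / den.sum())

    starts = range(0, n_loci, block_size)
    blocks = [(s, min(s + block_size, n_loci)) for s in starts]
    if len(blocks) < 2:
        return FstResult(pair=pair, fst=fst, se=float("nan"),
                         n_loci=n_loci, block_size=block_size)
    tot_num, tot_den = num.sum(), den.sum()
    theta = []
    for s, e in blocks:
        d = tot_den - den[s:e].sum()
        if d == 0:
            continue
        theta.append((tot_num - num[s:e].sum()) / d)
    theta = np.array(theta)
    nb = len(theta)
    se = float(np.sqrt((nb - 1) / nb * ((theta - theta.mean()) ** 2).sum()))
    return FstResult(pair=pair, fst=fst, se=se, n_loci=n_loci,
                     block_size=block_size)
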