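"""Geographic enrichment: chi-square scan over regions with smoothing.

Each common haplogroup (cohort frequency >= 1%) is tested for unequal
regional distribution with a Pearson chi-square test of homogeneous
proportions on the regions x {carrier, non-carrier} table (df = regions - 1,
no continuity correction).  Significance is reported in tiers: nominal
(p < alpha) and corrected (p < alpha / n_tests, Bonferroni).  Regions whose
denominator falls below a minimum are first folded into their geographically
nearest adjacent region (regional averaging on low-coverage regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .frequencies import FrequencyTable

__all__ = ["EnrichmentResult", "SmoothingPlan", "select_common",
           "chisq_equal_proportions", "correct_multiple", "smooth_regions",
           "enrichment_scan"]


@dataclass
class EnrichmentResult:
    haplogroup: str
    chi2: float
    df: int
    p: float
    tier: str = "ns"  # ns | nominal | corrected
    peak_region: str | None = None
    peak_freq: float = float("nan")
    mode: str = "all"
    smoothed_regions: tuple = ()


@dataclass
class SmoothingPlan:
    """Regional-averaging rule: regions whose denominator is below
    ``min_denominator`` merge into their nearest adjacent region (fewest
    hops; ties by larger donor denominator, then code)."""

    adjacency: dict
    min_denominator: int = 5
    applied: list = field(default_factory=list)  # (folded region, target)


def select_common(freq: FrequencyTable, min_freq: float = 0.01) -> list[str]:
    """Haplogroups at or above ``min_freq`` cohort-wide (raw) frequency."""
    raw = freq.raw
    return [h for h in freq.counts.index if raw[h] >= min_freq]


def smooth_regions(
    counts: pd.DataFrame, plan: SmoothingPlan
) -> tuple[pd.DataFrame, dict]:
    """Fold below-minimum regions into neighbours until all denominators
    meet the minimum.  ``counts`` is indexed by region with a ``total``
    column (denominator) plus any carrier-count columns, all summed on
    merge.  Returns the merged table and a provenance map
    {folded region: target region}.  Totals are conserved.
    """
    df = counts.copy()
    graph = nx.Graph(
        (a, b) for a, nbrs in plan.adjacency.items() for b in nbrs
    )
    provenance: dict[str, str] = {}
    while True:
        small = df.index[df["total"] < plan.min_denominator]
        if len(small) == 0:
            break
        r = min(small, key=lambda x: (df.at[x, "total"], x))
        if r not in graph:
            raise ValueError(f"region {r} below minimum but not in adjacency")
        lengths = nx.single_source_shortest_path_length(graph, r)
        others = [x for x in df.index if x != r and x in lengths]
        if not others:
            raise ValueError(f"region {r} below minimum with no reachable neighbor")
        target = min(others, key=lambda x: (lengths[x], -df.at[x, "total"], x))
        df.loc[target] += df.loc[r]
        df = df.drop(index=r)
        # chains: anything previously folded into r now points to target
        for k, v in list(provenance.items()):
            if v == r:
                provenance[k] = target
        provenance[r] = target
    plan.applied = sorted(provenance.items())
    return df, provenance


def chisq_equal_proportions(
    counts: pd.DataFrame, haplogroup: str = "", mode: str = "all",
    smoothed: tuple = (),
) -> EnrichmentResult:
    """Pearson chi-square of equal carrier proportions across regions.

    ``counts`` is indexed by region with columns ``carriers`` and ``total``.
    The R x 2 table (carriers vs non-carriers) is tested against homogeneous
    proportions; df = R - 1.
    """
    carriers = counts["carriers"].to_numpy(dtype=float)
    totals = counts["total"].to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = list(counts.index[counts["total"] <= 0])
        raise ValueError(f"regions with zero denominator: {bad} "
                         "(smoothing must remove them first)")
    if len(totals) < 2:
        raise ValueError("need at least 2 regions")
    table = np.column_stack([carriers, totals - carriers])
    df = len(totals) - 1
    pooled = carriers.sum() / totals.sum()
    if pooled in (0.0, 1.0):
        chi2, p = 0.0, 1.0
    else:
        expected = np.column_stack([totals * pooled, totals * (1 - pooled)])
        chi2 = float(((table - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df))
    freq = np.divide(carriers, totals)
    peak = int(np.argmax(freq))
    return EnrichmentResult(
        haplogroup=haplogroup, chi2=chi2, df=df, p=p,
        peak_region=str(counts.index[peak]), peak_freq=float(freq[peak]),
        mode=mode, smoothed_regions=tuple(smoothed),
    )


def correct_multiple(
    results: list[EnrichmentResult], n_tests: int, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Assign significance tiers: nominal when p < alpha, corrected when
    p < alpha / n_tests (Bonferroni)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    for res in results:
        if res.p < alpha / n_tests:
            res.tier = "corrected"
        elif res.p < alpha:
            res.tier = "nominal"
        else:
            res.tier = "ns"
    return results


def enrichment_scan(
    carrier_table: pd.DataFrame,
    totals: pd.Series,
    plan: SmoothingPlan | None = None,
    n_tests: int | None = None,
    alpha: float = 0.05,
    mode: str = "all",
) -> list[EnrichmentResult]:
    """Test every haplogroup row of ``carrier_table`` (haplogroup x region
    carrier counts, denominators ``totals``) for regional enrichment, with
    optional smoothing, and tier the p-values.  ``n_tests`` defaults to the
    number of tests actually run."""
    results = []
    for h in carrier_table.index:
        counts = pd.DataFrame(
            {"carriers": carrier_table.loc[h], "total": totals}
        )
        smoothed = ()
        if plan is not None:
            counts, prov = smooth_regions(counts, SmoothingPlan(
                adjacency=plan.adjacency, min_denominator=plan.min_denominator
            ))
            smoothed = tuple(sorted(prov))
        results.append(
            chisq_equal_proportions(counts, haplogroup=h, mode=mode,
                                    smoothed=smoothed)
        )
    return correct_multiple(results, n_tests or len(results), alpha)
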