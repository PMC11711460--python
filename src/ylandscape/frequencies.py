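"""Raw and census-scaled haplogroup frequencies.

Regional sampling in survey cohorts rarely matches the census distribution
(here: deliberate eastern oversampling), so the country-wide frequency of a
haplogroup is estimated as the census-weighted average of its regional
frequencies, F_h = sum_r w_r f_{h,r} with w_r = popsize_r / sum popsize,
rather than the raw carrier fraction.  Denominators are either all samples
or, for sublineage questions, the carriers of a major haplogroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .tree import CladeTree, ROOT

__all__ = ["FrequencyTable", "raw_frequencies", "scaled_frequencies",
           "within_major", "carrier_counts"]


@dataclass
class FrequencyTable:
    """Haplogroup x region counts with optional census scaling.

    ``counts`` holds carrier counts n_{h,r}; ``totals`` the per-region
    denominators.  After :func:`scaled_frequencies`, ``weights`` holds the
    census weights w_r (summing to 1) and ``scaled`` the country-wide
    frequency F_h = sum_r w_r f_{h,r}.
    """

    counts: pd.DataFrame
    totals: pd.Series
    mode: str = "all"
    weights: pd.Series | None = None
    scaled: pd.Series | None = None
    low_coverage: list = field(default_factory=list)

    @property
    def freq(self) -> pd.DataFrame:
        """Regional frequencies f_{h,r}; NaN where the denominator is 0."""
        return self.counts.div(self.totals, axis=1)

    @property
    def raw(self) -> pd.Series:
        """Unscaled cohort-wide frequency n_h / N."""
        return self.counts.sum(axis=1) / self.totals.sum()

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (haplogroup, region, n, f, w, F, mode)."""
        long = self.counts.stack().rename("n").reset_index()
        long.columns = ["haplogroup", "region", "n"]
        long["f"] = [self.freq.at[h, r] for h, r in zip(long.haplogroup, long.region)]
        if self.weights is not None:
            long["w"] = long["region"].map(self.weights)
            long["F"] = long["haplogroup"].map(self.scaled)
        long["mode"] = self.mode
        return long


def raw_frequencies(assignments: pd.DataFrame, regions=None) -> FrequencyTable:
    """Counts and frequencies of assigned haplogroups by region.

    ``assignments`` needs ``haplogroup`` and ``region`` columns; the
    haplogroups form a disjoint exhaustive partition, so per-region
    frequency columns sum to 1.
    """
    if len(assignments) == 0:
        raise ValueError("empty cohort")
    counts = pd.crosstab(assignments["haplogroup"], assignments["region"])
    if regions is not None:
        counts = counts.reindex(columns=list(regions), fill_value=0)
    totals = counts.sum(axis=0)
    return FrequencyTable(counts=counts, totals=totals, mode="all")


def scaled_frequencies(
    table: FrequencyTable,
    census: dict,
    zero_region_policy: str = "merge",
    adjacency: dict | None = None,
) -> FrequencyTable:
    """Census-scale a frequency table: F_h = sum_r w_r f_{h,r}.

    Regions present in the table but with a zero denominator either have
    their census weight folded into the nearest adjacent sampled region
    (``zero_region_policy="merge"``, requires ``adjacency``) or are dropped
    with the remaining weights renormalised (``"drop"``).  Raises when a
    table region has no census entry.
    """
    counts = table.counts.copy()
    totals = table.totals.copy()
    regions = list(counts.columns)
    missing = [r for r in regions if r not in census]
    if missing:
        raise ValueError(f"census entries missing for regions: {missing}")

    census_eff = {r: float(census[r]) for r in regions}
    zero = [r for r in regions if totals[r] == 0]
    if zero:
        if zero_region_policy == "merge":
            if adjacency is None:
                raise ValueError("merge policy requires an adjacency list")
            graph = nx.Graph(
                (a, b) for a, nbrs in adjacency.items() for b in nbrs
            )
            for r in sorted(zero):
                target = _nearest(graph, r, [x for x in regions if totals[x] > 0],
                                  totals)
                census_eff[target] += census_eff.pop(r)
                counts[target] += counts[r]
                counts = counts.drop(columns=r)
                totals = totals.drop(r)
                regions.remove(r)
        elif zero_region_policy == "drop":
            for r in zero:
                census_eff.pop(r)
                counts = counts.drop(columns=r)
                totals = totals.drop(r)
                regions.remove(r)
        else:
            raise ValueError(f"unknown zero_region_policy {zero_region_policy!r}")

    total_pop = sum(census_eff.values())
    weights = pd.Series({r: census_eff[r] / total_pop for r in regions})
    freq = counts.div(totals, axis=1)
    scaled = (freq * weights).sum(axis=1)
    return FrequencyTable(
        counts=counts, totals=totals, mode=table.mode,
        weights=weights, scaled=scaled, low_coverage=list(table.low_coverage),
    )


def _nearest(graph, source, candidates, totals):
    """Closest candidate by hop count; ties by larger denominator, then code."""
    if source not in graph:
        raise ValueError(f"region {source} not in adjacency")
    lengths = nx.single_source_shortest_path_length(graph, source)
    reachable = [c for c in candidates if c in lengths]
    if not reachable:
        raise ValueError(f"no sampled region reachable from {source}")
    return min(reachable, key=lambda c: (lengths[c], -totals[c], c))


def carrier_counts(
    assignments: pd.DataFrame, tree: CladeTree, regions=None
) -> pd.DataFrame:
    """Clade x region carrier counts; a sample carries every clade on its
    assignment's ancestor path (cumulative, unlike the disjoint partition of
    :func:`raw_frequencies`)."""
    at = pd.crosstab(assignments["haplogroup"], assignments["region"])
    if regions is not None:
        at = at.reindex(columns=list(regions), fill_value=0)
    clades = [c for c in tree.preorder() if c != ROOT]
    out = pd.DataFrame(0, index=clades, columns=at.columns)
    for assigned in at.index:
        if assigned == ROOT:
            continue
        if assigned not in tree.clades:
            raise ValueError(f"assigned clade {assigned} not in tree")
        for anc in tree.path(assigned):
            out.loc[anc] += at.loc[assigned]
    return out


def within_major(
    assignments: pd.DataFrame, tree: CladeTree, major: str, regions=None
) -> FrequencyTable:
    """Frequencies of ``major`` and its sublineages out of the per-region
    carriers of ``major``.  Regions with zero major carriers are flagged
    ``low_coverage`` (candidates for regional averaging)."""
    if major not in tree.clades or major == ROOT:
        raise ValueError(f"major haplogroup {major!r} not a clade in the tree")
    cc = carrier_counts(assignments, tree, regions=regions)
    totals = cc.loc[major]
    sub = [major] + tree.descendants(major)
    counts = cc.loc[sub]
    low = [r for r in counts.columns if totals[r] == 0]
    return FrequencyTable(
        counts=counts, totals=totals, mode=f"within:{major}", low_coverage=low
    )
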