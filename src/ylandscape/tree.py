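"""Haplogroup phylogeny from pairwise carrier-set containment.

For binary haploid variants with known ancestral state, a perfect phylogeny
exists iff no variant pair shows all three patterns (1,1), (1,0), (0,1)
among mutually genotyped samples (the three-gamete condition).  The tree is
assembled by classifying every variant pair as equivalent / nested /
disjoint / conflicting from the carrier-overlap counts (n11, n10, n01),
greedily dropping conflicting variants, collapsing equivalence classes to
clades, and reducing the containment partial order to its Hasse diagram.
Samples are then assigned to the deepest clade whose defining markers they
carry by majority, and clades are matched to published haplogroup labels
through a marker-alias table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, MISSING

__all__ = [
    "Clade", "CladeTree", "StructuralError",
    "filter_mac", "classify_pair", "pairwise_counts",
    "build_tree", "assign_samples", "annotate_clades",
]

ROOT = "ROOT"


class StructuralError(ValueError):
    """The containment diagram is not a tree (names the offending clades)."""


# ---------------------------------------------------------------------------
# pairwise classification


def classify_pair(a, b, universe=None, min_informative: int = 1) -> str:
    """Classify two carrier sets from their overlap counts.

    ``universe`` is the set of samples genotyped at both variants; when
    given, counts are restricted to it and the pair is ``ambiguous`` if it
    holds fewer than ``min_informative`` samples.  Relations:
    ``equivalent`` (identical carriers), ``a_over_b`` / ``b_over_a``
    (nesting), ``disjoint``, ``conflict`` (three-gamete violation), or
    ``ambiguous``.
    """
    a, b = set(a), set(b)
    if universe is not None:
        universe = set(universe)
        if len(universe) < min_informative:
            return "ambiguous"
        a &= universe
        b &= universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    return _relation(n11, n10, n01)


def _relation(n11: int, n10: int, n01: int) -> str:
    if n11 > 0 and n10 > 0 and n01 > 0:
        return "conflict"
    if n11 > 0 and n10 == 0 and n01 == 0:
        return "equivalent"
    if n11 > 0 and n01 == 0:
        return "a_over_b"
    if n11 > 0 and n10 == 0:
        return "b_over_a"
    if n11 == 0 and n10 > 0 and n01 > 0:
        return "disjoint"
    return "ambiguous"  # no informative overlap at all


def pairwise_counts(G: np.ndarray):
    """(n11, n10, n01) matrices over samples non-missing at both variants."""
    D = (G == 1).astype(np.float64)
    A = (G == 0).astype(np.float64)
    n11 = D @ D.T
    n10 = D @ A.T
    return n11.astype(np.int64), n10.astype(np.int64), n10.T.copy()


# ---------------------------------------------------------------------------
# MAC filter


def filter_mac(gm: GenotypeMatrix, min_mac: int = 5) -> GenotypeMatrix:
    """Keep variants with at least ``min_mac`` derived carriers among
    non-missing calls."""
    return gm.subset_variants(gm.derived_counts() >= min_mac)


# ---------------------------------------------------------------------------
# the clade tree


@dataclass
class Clade:
    name: str
    markers: list[str]
    parent: str | None
    children: list[str] = field(default_factory=list)
    members: set[str] = field(default_factory=set)
    label: str | None = None
    novel: bool = False

    @property
    def display(self) -> str:
        return self.label or self.name


class CladeTree:
    """Rooted tree of haplogroup clades; the root is the cohort ancestor."""

    def __init__(self, clades: dict[str, Clade]):
        if ROOT not in clades:
            raise ValueError("tree must contain a ROOT clade")
        self.clades = clades

    @property
    def root(self) -> Clade:
        return self.clades[ROOT]

    def __contains__(self, name) -> bool:
        return name in self.clades

    def __len__(self) -> int:
        return len(self.clades) - 1  # non-root clades

    def preorder(self) -> list[str]:
        out, stack = [], [ROOT]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.clades[n].children))
        return out

    def descendants(self, name: str) -> list[str]:
        out, stack = [], list(self.clades[name].children)
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.clades[n].children)
        return out

    def path(self, name: str) -> list[str]:
        """Root-exclusive ancestor path ending at ``name``."""
        out = []
        while name != ROOT:
            out.append(name)
            name = self.clades[name].parent
        return out[::-1]

    def member_family(self) -> set[frozenset]:
        """The family of non-root member sets (tree topology fingerprint:
        two containment trees are isomorphic iff these families match)."""
        return {frozenset(self.clades[c].members)
                for c in self.clades if c != ROOT}

    def validate(self) -> None:
        """Check containment and sibling-disjointness invariants."""
        for name, clade in self.clades.items():
            for ch in clade.children:
                if not self.clades[ch].members <= clade.members:
                    raise StructuralError(f"{ch} not contained in {name}")
            for i, a in enumerate(clade.children):
                for b in clade.children[i + 1:]:
                    if self.clades[a].members & self.clades[b].members:
                        raise StructuralError(f"siblings {a}, {b} overlap")

    def to_newick(self) -> str:
        def rec(name):
            clade = self.clades[name]
            bl = len(clade.markers)
            inner = ",".join(rec(c) for c in clade.children)
            label = clade.display.replace(" ", "_")
            if inner:
                return f"({inner}){label}:{bl}"
            return f"{label}:{bl}"

        return rec(ROOT) + ";"


# ---------------------------------------------------------------------------
# tree assembly


def build_tree(
    gm: GenotypeMatrix, min_informative: int = 1
) -> tuple[CladeTree, list[str]]:
    """Assemble the clade tree from a MAC-filtered binary matrix.

    Conflicting variants (three-gamete violations) are removed greedily —
    most conflicts first, ties broken by lower derived count, then position,
    then name — before assembly; the dropped variant ids are returned
    alongside the tree.  Raises :class:`StructuralError` when the surviving
    containment diagram is not a tree.
    """
    n_var = gm.n_variants
    samples = list(gm.samples)
    # zero-carrier variants define no clade; ignore them up front
    gm = gm.subset_variants(gm.derived_counts() > 0)

    G = gm.G
    ids = list(gm.variants.index)
    pos = gm.variants["pos"].to_numpy()
    mac = gm.derived_counts()

    n11, n10, n01 = pairwise_counts(G)
    informative = n11 + n10 + n01

    conflict = (n11 > 0) & (n10 > 0) & (n01 > 0)
    np.fill_diagonal(conflict, False)

    dropped: list[str] = []
    alive = np.ones(len(ids), dtype=bool)
    while True:
        counts = conflict.sum(axis=1)
        worst = counts.max() if len(counts) else 0
        if worst == 0:
            break
        cand = np.flatnonzero(counts == worst)
        v = min(cand, key=lambda i: (mac[i], pos[i], ids[i]))
        dropped.append(ids[v])
        alive[v] = False
        conflict[v, :] = False
        conflict[:, v] = False

    keep = np.flatnonzero(alive)
    ids_k = [ids[i] for i in keep]
    G = G[keep]
    n11, n10, n01 = n11[np.ix_(keep, keep)], n10[np.ix_(keep, keep)], n01[np.ix_(keep, keep)]
    informative = informative[np.ix_(keep, keep)]
    pos_k = pos[keep]

    # collapse equivalence classes (union over the equivalence relation)
    m = len(ids_k)
    eq = (n11 > 0) & (n10 == 0) & (n01 == 0) & (informative >= min_informative)
    parent_uf = list(range(m))

    def find(x):
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            if eq[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent_uf[rj] = ri

    classes: dict[int, list[int]] = {}
    for i in range(m):
        classes.setdefault(find(i), []).append(i)
    class_list = sorted(
        classes.values(), key=lambda idx: (pos_k[idx].min(), min(ids_k[i] for i in idx))
    )

    # per-class carrier sets: derived at a majority of non-missing markers
    n_samp = G.shape[1]
    car, info_mask = [], []
    for idx in class_list:
        sub = G[idx]
        nn = (sub != MISSING).sum(axis=0)
        nd = (sub == 1).sum(axis=0)
        info_mask.append(nn > 0)
        car.append((nn > 0) & (2 * nd >= nn))
    car = np.array(car)
    info_mask = np.array(info_mask)

    k = len(class_list)
    rel = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            if i == j:
                rel[i, j] = "equivalent"
                continue
            u = info_mask[i] & info_mask[j]
            if u.sum() < min_informative:
                rel[i, j] = "ambiguous"
                continue
            a, b = car[i] & u, car[j] & u
            rel[i, j] = _relation(
                int((a & b).sum()), int((a & ~b).sum()), int((~a & b).sum())
            )

    for i in range(k):
        for j in range(i + 1, k):
            if rel[i, j] == "conflict":
                mi = [ids_k[x] for x in class_list[i]]
                mj = [ids_k[x] for x in class_list[j]]
                raise StructuralError(
                    f"unresolved conflict between clades {mi} and {mj}"
                )
            if rel[i, j] == "equivalent":
                # residual equivalence across classes (missing-data edge
                # case); merge conservatively
                class_list[i].extend(class_list[j])
                class_list[j] = []
    class_list = [c for c in class_list if c]
    if len(class_list) != k:  # re-derive after merges
        return _assemble(gm, class_list, ids_k, pos_k, G, samples, min_informative, dropped)

    return _finish(class_list, ids_k, pos_k, car, info_mask, rel, samples, G, dropped)


def _assemble(gm, class_list, ids_k, pos_k, G, samples, min_informative, dropped):
    # recompute carrier sets and relations after class merges
    car, info_mask = [], []
    for idx in class_list:
        sub = G[idx]
        nn = (sub != MISSING).sum(axis=0)
        nd = (sub == 1).sum(axis=0)
        info_mask.append(nn > 0)
        car.append((nn > 0) & (2 * nd >= nn))
    car = np.array(car)
    info_mask = np.array(info_mask)
    k = len(class_list)
    rel = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            if i == j:
                rel[i, j] = "equivalent"
                continue
            u = info_mask[i] & info_mask[j]
            if u.sum() < min_informative:
                rel[i, j] = "ambiguous"
                continue
            a, b = car[i] & u, car[j] & u
            rel[i, j] = _relation(
                int((a & b).sum()), int((a & ~b).sum()), int((~a & b).sum())
            )
    return _finish(class_list, ids_k, pos_k, car, info_mask, rel, samples, G, dropped)


def _finish(class_list, ids_k, pos_k, car, info_mask, rel, samples, G, dropped):
    k = len(class_list)
    sizes = car.sum(axis=1)

    clades = {ROOT: Clade(ROOT, [], None, members=set(samples))}
    names = [f"C{i + 1:03d}" for i in range(k)]

    order = sorted(range(k), key=lambda i: (-sizes[i], pos_k[class_list[i]].min()))
    for i in range(k):
        ancestors = [j for j in range(k) if rel[j, i] == "a_over_b"]
        # the candidate ancestors must form a containment chain
        ancestors.sort(key=lambda j: sizes[j])
        for a, b in zip(ancestors, ancestors[1:]):
            # ambiguous pairs are unordered, not incomparable: the variant
            # still attaches at the lowest certain ancestor
            if rel[b, a] not in ("a_over_b", "ambiguous"):
                ma = [ids_k[x] for x in class_list[a]]
                mb = [ids_k[x] for x in class_list[b]]
                raise StructuralError(
                    f"clade {names[i]} has incomparable ancestors "
                    f"defined by {ma} and {mb}"
                )
    parent_of = {}
    for i in range(k):
        ancestors = [j for j in range(k) if rel[j, i] == "a_over_b"]
        parent_of[i] = min(ancestors, key=lambda j: sizes[j]) if ancestors else None

    for i in order:
        idx = sorted(class_list[i], key=lambda x: (pos_k[x], ids_k[x]))
        markers = [ids_k[x] for x in idx]
        members = {samples[s] for s in np.flatnonzero(car[i])}
        pname = ROOT if parent_of[i] is None else names[parent_of[i]]
        clades[names[i]] = Clade(names[i], markers, pname, members=members)
    for i in range(k):
        pname = ROOT if parent_of[i] is None else names[parent_of[i]]
        clades[pname].children.append(names[i])
    for c in clades.values():
        c.children.sort(key=lambda n: (min(
            pos_k[x] for x in class_list[names.index(n)]), n))

    tree = CladeTree(clades)
    # a sample derived for a child's markers descends from the parent's
    # mutation too, even if missing there: membership is cumulative
    for name in reversed(tree.preorder()):
        clade = tree.clades[name]
        if clade.parent is not None:
            tree.clades[clade.parent].members |= clade.members
    return tree, dropped


# ---------------------------------------------------------------------------
# sample assignment


def assign_samples(tree: CladeTree, gm: GenotypeMatrix) -> pd.Series:
    """Assign each sample to the deepest clade for which it is derived at a
    majority of the clade's non-missing defining markers, requiring the same
    along every ancestor.  An ancestor with every defining marker missing is
    passable, but only positive evidence (a derived majority at one or more
    genotyped markers) can be the final assignment.  Samples qualifying
    nowhere stay at ROOT."""
    row_of = {v: i for i, v in enumerate(gm.variants.index)}
    n = gm.n_samples
    evid, vac = {}, {}
    for name, clade in tree.clades.items():
        if name == ROOT:
            continue
        idx = [row_of[m] for m in clade.markers if m in row_of]
        if not idx:
            evid[name] = np.zeros(n, dtype=bool)
            vac[name] = np.ones(n, dtype=bool)
            continue
        sub = gm.G[idx]
        nn = (sub != MISSING).sum(axis=0)
        nd = (sub == 1).sum(axis=0)
        evid[name] = (nn > 0) & (2 * nd >= nn)
        vac[name] = nn == 0

    assignment = np.array([ROOT] * n, dtype=object)
    best_depth = np.zeros(n, dtype=int)
    reach = {ROOT: np.ones(n, dtype=bool)}
    depth = {ROOT: 0}
    for name in tree.preorder():
        if name == ROOT:
            continue
        parent = tree.clades[name].parent
        depth[name] = depth[parent] + 1
        reach[name] = reach[parent] & (evid[name] | vac[name])
        hit = reach[name] & evid[name] & (depth[name] > best_depth)
        assignment[hit] = name
        best_depth[hit] = depth[name]
    return pd.Series(assignment, index=gm.samples, name="haplogroup")


# ---------------------------------------------------------------------------
# annotation


def annotate_clades(tree: CladeTree, aliases) -> tuple[CladeTree, dict]:
    """Label clades through a marker-alias table and flag novel ones.

    ``aliases`` is a DataFrame with ``marker`` and ``label`` columns (or a
    mapping marker -> label).  A clade whose marker set intersects the table
    gets the published label (ties: warning, lexicographically first label
    wins); others get a systematic label — parent label plus ordinal — and
    are flagged novel.  Returns the tree (modified in place) and a ledger
    with the clade and novelty counts and the novelty percentage to one
    decimal.
    """
    if isinstance(aliases, dict):
        alias_map = dict(aliases)
    else:
        if aliases["marker"].duplicated().any():
            raise ValueError("marker names in the alias table must be unique")
        alias_map = dict(zip(aliases["marker"], aliases["label"]))

    tree.root.label = ROOT
    n_novel = 0
    for name in tree.preorder():
        if name == ROOT:
            continue
        clade = tree.clades[name]
        labels = sorted({alias_map[m] for m in clade.markers if m in alias_map})
        if labels:
            if len(labels) > 1:
                warnings.warn(
                    f"clade {name}: aliases disagree {labels}; using {labels[0]}"
                )
            clade.label = labels[0]
            clade.novel = False
        else:
            parent = tree.clades[clade.parent]
            ordinal = sum(
                1 for ch in parent.children if tree.clades[ch].novel
            ) + 1
            clade.label = f"{parent.display}*{ordinal}"
            clade.novel = True
            n_novel += 1
    n_clades = len(tree)
    ledger = dict(
        n_clades=n_clades,
        n_novel=n_novel,
        pct_novel=round(100.0 * n_novel / n_clades, 1) if n_clades else 0.0,
    )
    return tree, ledger
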