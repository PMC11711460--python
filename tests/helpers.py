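"""Shared test utilities: independent oracles and small builders."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ylandscape.matrix import GenotypeMatrix
from ylandscape.tree import Clade, CladeTree, ROOT


def make_matrix(G, ids=None, positions=None, samples=None, **site_fields):
    """Build a GenotypeMatrix from a plain int array with clean site stats."""
    G = np.asarray(G, dtype=np.int8)
    n_var, n_samp = G.shape
    ids = ids or [f"v{i + 1}" for i in range(n_var)]
    positions = positions if positions is not None else [100 + 10 * i for i in range(n_var)]
    samples = samples or [f"s{j + 1}" for j in range(n_samp)]
    variants = pd.DataFrame(
        {
            "pos": positions,
            "ref": ["A"] * n_var,
            "alt": ["G"] * n_var,
            "filter": ["PASS"] * n_var,
            "dp_mean": [20.0] * n_var,
            "fs": [1.0] * n_var,
            "mq": [58.0] * n_var,
        },
        index=pd.Index(ids, name="id"),
    )
    for key, values in site_fields.items():
        variants[key] = values
    return GenotypeMatrix(variants, G, samples)


def make_clade_tree(spec: dict, members: dict | None = None) -> CladeTree:
    """Build a CladeTree from {name: (parent, markers)} plus member sets."""
    members = members or {}
    all_members = set()
    for m in members.values():
        all_members |= set(m)
    clades = {ROOT: Clade(ROOT, [], None, members=set(all_members))}
    for name, (parent, markers) in spec.items():
        clades[name] = Clade(name, list(markers), parent,
                             members=set(members.get(name, ())))
    for name, (parent, _) in spec.items():
        clades[parent].children.append(name)
    return CladeTree(clades)


def three_gamete_compatible(G: np.ndarray) -> bool:
    """Exhaustive pair-scan oracle for perfect-phylogeny compatibility of a
    complete binary matrix with known ancestral state 0."""
    n = G.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = G[i] == 1, G[j] == 1
            if (a & b).any() and (a & ~b).any() and (~a & b).any():
                return False
    return True


def truth_member_family(sim_tree, truth_samples, min_members=5):
    """Member-set family of the generating genealogy's clades, restricted to
    clades carried by at least ``min_members`` samples (the resolvable part
    of the truth under a MAC filter)."""
    hap = truth_samples.set_index("sample_id")["true_haplogroup"]
    family = set()
    for clade in sim_tree.nodes:
        if clade == sim_tree.ROOT:
            continue
        leaves = sim_tree.leaf_set(clade)
        mem = frozenset(hap.index[hap.isin(leaves)])
        if len(mem) >= min_members:
            family.add(mem)
    return family


def assignment_accuracy(sim_tree, truth_samples, recon_tree, assigned) -> float:
    """Fraction of samples whose assigned reconstructed clade corresponds
    (through its defining markers) to the deepest resolvable clade on their
    true root-to-leaf path."""
    marker_truth = {m: c for c in sim_tree.nodes if c != sim_tree.ROOT
                    for m in sim_tree.nodes[c].markers}
    clade_truth = {ROOT: sim_tree.ROOT}
    for name, clade in recon_tree.clades.items():
        if name == ROOT:
            continue
        tc = {marker_truth[m] for m in clade.markers if m in marker_truth}
        # marker classes merged across nested truth clades map to the deepest
        clade_truth[name] = (
            max(tc, key=lambda c: len(sim_tree.path(c))) if tc else None
        )
    resolvable = set(clade_truth.values())
    hap = truth_samples.set_index("sample_id")["true_haplogroup"]
    hits = []
    for s in assigned.index:
        expected = sim_tree.ROOT
        for node in sim_tree.path(hap[s]):
            if node in resolvable:
                expected = node
        hits.append(clade_truth[assigned[s]] == expected)
    return float(np.mean(hits))
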