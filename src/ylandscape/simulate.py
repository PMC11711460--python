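"""Synthetic Y-chromosome cohort generator.

Emulates the statistical structure the downstream analyses assume: a cohort
of men sampled over 19 regions with eastern oversampling, a known haplogroup
genealogy with region-dependent leaf frequencies (east- and west-enriched
clines), Poisson mutation accumulation on branches, QC-failing decoy
variants, corrupted birthplace metadata, and autosomal dosages with an
east-west ancestry gradient.  Every draw is taken from a single seeded
generator, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geography import RegionVocabulary, default_vocabulary
from .matrix import GenotypeMatrix, HET, MISSING
from .vcfio import write_bed, write_vcf

__all__ = [
    "DemographyConfig",
    "NoiseConfig",
    "TrueClade",
    "TrueTree",
    "SimulatedCohort",
    "simulate_tree",
    "simulate_cohort",
    "simulate_dosages",
    "simulate_two_demes",
]

POS_LO, POS_HI = 2_700_000, 26_000_000  # callable chrY coordinate span


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class DemographyConfig:
    """Regional sampling frame for the synthetic cohort.

    ``sampling_weights`` may differ from the census weights to emulate the
    survey's eastern oversampling; the census weights are what the scaled
    frequency estimator corrects back to.
    """

    regions: tuple[str, ...]
    census_sizes: dict[str, int]
    sampling_weights: dict[str, float]
    n_samples: int = 1833
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if set(self.sampling_weights) != set(self.regions):
            raise ValueError("sampling_weights regions do not match region list")
        for r in self.regions:
            if self.census_sizes[r] <= 0:
                raise ValueError(f"census size for {r} must be positive")
        total = sum(self.sampling_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sampling_weights sum to {total}, not 1")

    @classmethod
    def default(
        cls,
        vocab: RegionVocabulary | None = None,
        n_samples: int = 1833,
        seed: int = 0,
        oversample_east: float = 1.8,
    ) -> "DemographyConfig":
        """Census-proportional sampling tilted east by ``oversample_east``.

        Weight of region r is census_r * (0.6 + oversample_east * east_r),
        normalised; oversample_east=0 gives census-proportional sampling.
        """
        vocab = vocab or default_vocabulary()
        raw = {
            r: vocab.census[r] * (0.6 + oversample_east * vocab.east[r])
            for r in vocab.codes
        }
        tot = sum(raw.values())
        return cls(
            regions=tuple(vocab.codes),
            census_sizes=dict(vocab.census),
            sampling_weights={r: w / tot for r, w in raw.items()},
            n_samples=n_samples,
            seed=seed,
        )

    def census_weights(self) -> dict[str, float]:
        tot = sum(self.census_sizes[r] for r in self.regions)
        return {r: self.census_sizes[r] / tot for r in self.regions}


@dataclass(frozen=True)
class NoiseConfig:
    """Artifact rates for the generator's QC-failure and metadata decoys.

    ``frac_fail_*`` and ``frac_nonpass`` are proportions of decoy variants
    (relative to the clean variant count) violating each QC threshold;
    ``frac_mask`` places decoys inside the mappability exclusion mask and
    ``frac_low_call`` emits sites whose call rate falls below the QC
    threshold.  Metadata corruption rates are per sample and mutually
    exclusive.
    """

    missing_rate: float = 0.01
    het_artifact_rate: float = 0.002
    frac_fail_fs: float = 0.02
    frac_fail_mq: float = 0.02
    frac_fail_dp: float = 0.02
    frac_nonpass: float = 0.05
    frac_mask: float = 0.02
    frac_low_call: float = 0.02
    n_monomorphic: int = 20
    frac_missing_geo: float = 4 / 1833
    frac_foreign: float = 24 / 1833
    frac_missing_father: float = 400 / 1833
    frac_relative: float = 0.084
    n_high_missing_samples: int = 2

    def __post_init__(self):
        for name in (
            "missing_rate", "het_artifact_rate", "frac_fail_fs", "frac_fail_mq",
            "frac_fail_dp", "frac_nonpass", "frac_mask", "frac_low_call",
            "frac_missing_geo", "frac_foreign", "frac_missing_father",
            "frac_relative",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if (self.frac_missing_geo + self.frac_foreign + self.frac_missing_father) > 1:
            raise ValueError("metadata corruption rates sum above 1")

    @classmethod
    def none(cls) -> "NoiseConfig":
        """The noiseless regime: every variant clean, metadata intact."""
        return cls(
            missing_rate=0.0, het_artifact_rate=0.0, frac_fail_fs=0.0,
            frac_fail_mq=0.0, frac_fail_dp=0.0, frac_nonpass=0.0,
            frac_mask=0.0, frac_low_call=0.0, n_monomorphic=0,
            frac_missing_geo=0.0, frac_foreign=0.0, frac_missing_father=0.0,
            frac_relative=0.0, n_high_missing_samples=0,
        )


# ---------------------------------------------------------------------------
# the true genealogy


@dataclass
class TrueClade:
    name: str
    markers: list[str]
    branch_length: float  # expected private mutations per lineage on branch
    parent: str | None
    children: list[str] = field(default_factory=list)


class TrueTree:
    """The genealogy genotypes are simulated on.

    ``leaf_freqs`` is a leaves x regions table; each region column is a
    probability distribution over leaf haplogroups.  ``leaf_beta`` holds the
    east-west log-linear cline coefficient of each leaf (positive = enriched
    in the east).
    """

    ROOT = "ROOT"

    def __init__(self, nodes: dict[str, TrueClade], leaf_freqs: pd.DataFrame,
                 leaf_beta: dict[str, float], forced_gradient=()):
        self.nodes = nodes
        self.leaf_freqs = leaf_freqs
        self.leaf_beta = leaf_beta
        self.forced_gradient = list(forced_gradient)
        colsums = leaf_freqs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("leaf frequency columns must each sum to 1")
        for node in nodes.values():
            if node.branch_length < 0:
                raise ValueError("branch lengths must be >= 0")

    @property
    def leaves(self) -> list[str]:
        return [n for n, c in self.nodes.items() if not c.children]

    def path(self, leaf: str) -> list[str]:
        """Root-to-leaf list of non-root clade names."""
        out = []
        node = leaf
        while node != self.ROOT:
            out.append(node)
            node = self.nodes[node].parent
        return out[::-1]

    def leaf_set(self, name: str) -> set[str]:
        """Leaves descending from (or equal to) a clade."""
        stack, out = [name], set()
        while stack:
            n = stack.pop()
            kids = self.nodes[n].children
            if kids:
                stack.extend(kids)
            else:
                out.add(n)
        return out

    def descendants(self, name: str) -> set[str]:
        """All strict descendant clades of ``name``."""
        stack, out = list(self.nodes[name].children), set()
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(self.nodes[n].children)
        return out

    @property
    def gradient_leaves(self) -> list[str]:
        """The leaves with deliberately injected strong east-west clines
        (one east-enriched, one west-enriched)."""
        if self.forced_gradient:
            return list(self.forced_gradient)
        return [l for l in self.leaves if abs(self.leaf_beta[l]) >= 2.0]


def simulate_tree(
    config: DemographyConfig,
    depth: int = 3,
    branching: int = 2,
    seed: int | None = None,
    markers_per_clade: tuple[int, int] = (2, 4),
    branch_length_range: tuple[float, float] = (0.5, 1.5),
    vocab: RegionVocabulary | None = None,
) -> TrueTree:
    """Build a balanced ``branching``-ary genealogy of the given depth.

    Each non-root clade carries 2-4 equivalent defining markers (haplogroup
    branches are typically supported by several equivalent SNPs) and a branch
    length in expected private mutations per lineage.  Leaf haplogroup
    frequencies follow log-linear east-west clines; the first leaf is forced
    east-enriched and the second west-enriched so both directions of the
    geographic gradient are always present.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    vocab = vocab or default_vocabulary()

    nodes = {TrueTree.ROOT: TrueClade(TrueTree.ROOT, [], 0.0, None)}
    counter = 0

    def grow(parent: str, code: str, level: int):
        nonlocal counter
        if level > depth:
            return
        for i in range(branching):
            child_code = code + chr(ord("A") + i)
            name = f"HG-{child_code}"
            n_mark = int(rng.integers(markers_per_clade[0], markers_per_clade[1] + 1))
            markers = []
            for _ in range(n_mark):
                counter += 1
                markers.append(f"M{counter:04d}")
            bl = float(rng.uniform(*branch_length_range))
            nodes[name] = TrueClade(name, markers, bl, parent)
            nodes[parent].children.append(name)
            grow(name, child_code, level + 1)

    grow(TrueTree.ROOT, "", 1)

    leaves = [n for n, c in nodes.items() if not c.children]
    regions = list(config.regions)
    east = np.array([vocab.east.get(r, 0.5) for r in regions])

    beta = rng.normal(0.0, 1.2, size=len(leaves))
    base_w = rng.dirichlet(np.full(len(leaves), 2.0))
    forced: list[str] = []
    if len(leaves) >= 2:
        # two forced clines with major-lineage base shares: a dominant
        # east-enriched lineage and a substantial west-enriched one,
        # mirroring the N1a1 / I1a split of the Finnish Y landscape
        # (country-wide shares land near 0.64 and 0.25 after the cline)
        beta[0], beta[1] = 2.5, -1.5
        forced = [leaves[0], leaves[1]]
        if len(leaves) > 2:
            rest = base_w[2:]
            base_w = np.concatenate([[0.30, 0.55],
                                     rest / rest.sum() * 0.15])
        else:
            base_w = np.array([0.35, 0.65])
    base = np.log(base_w + 1e-12)
    score = base[:, None] + beta[:, None] * east[None, :]
    freqs = np.exp(score - score.max(axis=0))
    freqs = freqs / freqs.sum(axis=0)
    leaf_freqs = pd.DataFrame(freqs, index=leaves, columns=regions)
    return TrueTree(nodes, leaf_freqs, dict(zip(leaves, beta)),
                    forced_gradient=forced)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort plus writers for the on-disk formats.

    ``gm`` is the raw (pre-QC) genotype matrix; its ``variants`` table
    carries ``truth_class`` (clean / decoy_* / monomorphic) and
    ``true_clade``.  ``truth_samples`` records each sample's true region and
    haplogroup regardless of metadata corruption.
    """

    gm: GenotypeMatrix
    metadata: pd.DataFrame
    truth_samples: pd.DataFrame
    mask: list[tuple[int, int]]
    tree: TrueTree
    demography: DemographyConfig
    noise: NoiseConfig

    def write_vcf(self, path):
        write_vcf(path, self.gm)

    def write_metadata(self, path):
        self.metadata.to_csv(path, sep="\t", index=False)

    def write_truth(self, path):
        self.truth_samples.to_csv(path, sep="\t", index=False)

    def write_mask(self, path):
        write_bed(path, self.mask)


def _unique_positions(rng, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(POS_LO, POS_HI, size=int(n * 1.2) + 16))
    while len(pos) < n:
        pos = np.unique(
            np.concatenate([pos, rng.integers(POS_LO, POS_HI, size=n)])
        )
    return rng.permutation(pos)[:n]


def simulate_cohort(
    tree: TrueTree,
    demo: DemographyConfig,
    noise: NoiseConfig | None = None,
    include_private: bool = True,
) -> SimulatedCohort:
    """Draw a cohort from the genealogy and emit genotypes plus metadata.

    Each sample is drawn region-first (sampling weights), then a leaf
    haplogroup from that region's distribution.  The sample is derived at
    every defining marker on its root-to-leaf path and accumulates
    Poisson(branch length) private mutations on each path branch.  Decoy
    variants violating each QC rule and corrupted metadata are injected per
    the noise configuration.
    """
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(demo.seed)
    n = demo.n_samples
    regions = list(demo.regions)
    weights = np.array([demo.sampling_weights[r] for r in regions])
    samples = [f"S{i:05d}" for i in range(n)]

    region_idx = rng.choice(len(regions), size=n, p=weights)
    leaves = list(tree.leaf_freqs.index)
    leaf_idx = np.empty(n, dtype=int)
    for ri, r in enumerate(regions):
        sel = np.flatnonzero(region_idx == ri)
        if len(sel):
            p = tree.leaf_freqs[r].to_numpy()
            leaf_idx[sel] = rng.choice(len(leaves), size=len(sel), p=p)
    sample_leaf = [leaves[i] for i in leaf_idx]
    sample_region = [regions[i] for i in region_idx]

    # membership of each clade = samples whose leaf descends from it
    clade_names = [c for c in tree.nodes if c != TrueTree.ROOT]
    leaf_arr = np.array(leaf_idx)
    leaf_pos = {l: i for i, l in enumerate(leaves)}
    member_mask = {}
    for c in clade_names:
        ls = np.array([leaf_pos[l] for l in tree.leaf_set(c)])
        member_mask[c] = np.isin(leaf_arr, ls)

    rows: list[dict] = []
    gt_rows: list[np.ndarray] = []

    def clean_stats():
        return dict(
            dp_mean=float(rng.uniform(15, 30)),
            fs=float(rng.uniform(0, 5)),
            mq=float(rng.uniform(55, 60)),
            filter="PASS",
        )

    # tree-defining markers
    for c in sorted(clade_names):
        for m in tree.nodes[c].markers:
            rows.append(dict(id=m, truth_class="clean", true_clade=c, **clean_stats()))
            gt_rows.append(member_mask[c].astype(np.int8))

    # private mutations: Poisson(branch length) singletons per path branch
    if include_private:
        priv_counter = 0
        for c in sorted(clade_names):
            members = np.flatnonzero(member_mask[c])
            if len(members) == 0:
                continue
            counts = rng.poisson(tree.nodes[c].branch_length, size=len(members))
            for s_i, k in zip(members, counts):
                for _ in range(k):
                    priv_counter += 1
                    g = np.zeros(n, dtype=np.int8)
                    g[s_i] = 1
                    rows.append(dict(
                        id=f"P{priv_counter:05d}", truth_class="clean_private",
                        true_clade=c, **clean_stats(),
                    ))
                    gt_rows.append(g)

    n_clean = len(rows)

    # decoy variants violating each QC rule
    def decoy_gt():
        p = rng.uniform(0.05, 0.5)
        return (rng.random(n) < p).astype(np.int8)

    def add_decoys(count, truth_class, override=None):
        for i in range(count):
            stats = clean_stats()
            if override is not None:
                stats.update(override())
            rows.append(dict(id=f"D_{truth_class}_{i:04d}",
                             truth_class=truth_class, true_clade="", **stats))
            gt_rows.append(decoy_gt())

    add_decoys(round(noise.frac_fail_fs * n_clean), "decoy_fs",
               lambda: dict(fs=float(rng.uniform(14, 60))))
    add_decoys(round(noise.frac_fail_mq * n_clean), "decoy_mq",
               lambda: dict(mq=float(rng.uniform(20, 49))))
    add_decoys(round(noise.frac_fail_dp * n_clean), "decoy_dp",
               lambda: dict(dp_mean=float(rng.uniform(2, 9.5))))
    add_decoys(round(noise.frac_nonpass * n_clean), "decoy_nonpass",
               lambda: dict(filter="FAIL_QUAL"))
    add_decoys(round(noise.frac_mask * n_clean), "decoy_mask")
    for i in range(noise.n_monomorphic):
        rows.append(dict(id=f"D_monomorphic_{i:04d}", truth_class="monomorphic",
                         true_clade="", **clean_stats()))
        gt_rows.append(np.zeros(n, dtype=np.int8))
    add_decoys(round(noise.frac_low_call * n_clean), "decoy_lowcall")
    for r, g in zip(rows, gt_rows):
        if r["truth_class"] == "decoy_lowcall":
            g[rng.random(n) < rng.uniform(0.10, 0.30)] = MISSING

    G = np.vstack(gt_rows) if gt_rows else np.empty((0, n), dtype=np.int8)
    variants = pd.DataFrame(rows)

    # positions; mask decoys get intervals covering their positions
    positions = _unique_positions(rng, len(variants))
    variants["pos"] = positions
    mask: list[tuple[int, int]] = []
    is_mask_decoy = variants["truth_class"].to_numpy() == "decoy_mask"
    for pos in sorted(variants.loc[is_mask_decoy, "pos"]):
        mask.append((int(pos) - 1, int(pos)))

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=len(variants))
    alt_i = (ref_i + rng.integers(1, 4, size=len(variants))) % 4
    variants["ref"] = bases[ref_i]
    variants["alt"] = bases[alt_i]

    # genotype-level noise over the whole matrix
    if noise.het_artifact_rate > 0 or noise.missing_rate > 0:
        u = rng.random(G.shape)
        if noise.het_artifact_rate > 0:
            G[u < noise.het_artifact_rate] = HET
        if noise.missing_rate > 0:
            miss = (u >= noise.het_artifact_rate) & (
                u < noise.het_artifact_rate + noise.missing_rate
            )
            G[miss] = MISSING

    if noise.n_high_missing_samples > 0:
        chosen = rng.choice(n, size=min(noise.n_high_missing_samples, n),
                            replace=False)
        for s_i in chosen:
            drop = rng.random(G.shape[0]) < 0.85
            G[drop, s_i] = MISSING

    # metadata with corruption
    birth_year = rng.integers(1923, 1980, size=n)
    is_relative = rng.random(n) < noise.frac_relative
    cat = rng.random(n)
    p_geo, p_for, p_father = (noise.frac_missing_geo, noise.frac_foreign,
                              noise.frac_missing_father)
    own = list(sample_region)
    father = list(sample_region)
    for i in range(n):
        if cat[i] < p_geo:
            own[i] = father[i] = None
        elif cat[i] < p_geo + p_for:
            own[i] = father[i] = "__FOREIGN__"
        elif cat[i] < p_geo + p_for + p_father:
            father[i] = None
    metadata = pd.DataFrame(dict(
        sample_id=samples, own_region=own, father_region=father,
        birth_year=birth_year, is_relative=is_relative,
    ))
    foreign = default_vocabulary().foreign_code
    metadata = metadata.replace("__FOREIGN__", foreign)

    truth = pd.DataFrame(dict(
        sample_id=samples, true_region=sample_region, true_haplogroup=sample_leaf,
    ))

    variants = variants.set_index("id")[
        ["pos", "ref", "alt", "filter", "dp_mean", "fs", "mq",
         "truth_class", "true_clade"]
    ]
    order = np.argsort(variants["pos"].to_numpy(), kind="stable")
    variants = variants.iloc[order]
    G = G[order]

    gm = GenotypeMatrix(variants, G, samples)
    return SimulatedCohort(gm, metadata, truth, mask, tree, demo, noise)


# ---------------------------------------------------------------------------
# autosomal structure


def simulate_dosages(
    sample_regions,
    vocab: RegionVocabulary | None = None,
    n_loci: int = 500,
    cline_sd: float = 0.15,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Autosomal dosage matrix (samples x loci) with an east-west ancestry
    gradient: per-locus allele frequencies shift linearly with the region's
    east coordinate, so PC1 of the dosages tracks geography."""
    vocab = vocab or default_vocabulary()
    rng = np.random.default_rng(seed)
    east = np.array([vocab.east.get(r, 0.5) for r in sample_regions])
    p0 = rng.uniform(0.1, 0.9, size=n_loci)
    slope = rng.normal(0.0, cline_sd, size=n_loci)
    p = np.clip(p0[None, :] + slope[None, :] * (east[:, None] - east.mean()),
                0.01, 0.99)
    dos = rng.binomial(2, p).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    return pd.DataFrame(
        dos,
        index=[f"S{i:05d}" for i in range(len(east))],
        columns=[f"L{j:05d}" for j in range(n_loci)],
    )


def simulate_two_demes(
    n1: int, n2: int, n_loci: int, fst: float, seed: int = 0
):
    """Allele counts for two demes under the Balding-Nichols model.

    Returns (ac1, n1_chrom, ac2, n2_chrom): per-locus derived-allele counts
    and chromosome totals.  The drift parameter equals the expected Hudson
    F_ST between the demes.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    if fst > 0:
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    else:
        p1 = p2 = p_anc
    ac1 = rng.binomial(n1, p1)
    ac2 = rng.binomial(n2, p2)
    return ac1, n1, ac2, n2
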