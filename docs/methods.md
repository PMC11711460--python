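# Methods

This note documents the models, rules and numerical choices behind
`ylandscape`, what the synthetic cohort generator does and does not
emulate, and the design decisions taken where several reasonable options
existed.

## The analysis model

The pipeline treats the Y chromosome as a single non-recombining locus.
Every derived allele marks a clade of patrilineal descendants, so with a
known ancestral state (the reference allele) the carrier sets of variants
must be laminar — nested or disjoint — whenever the data fit a tree.  The
pipeline's stages follow from that premise:

1. **Quality control.** Haploid male Y calls cannot be heterozygous;
   diploid "0/1" records are treated as artifacts and set missing *before*
   any per-site statistic (call rate, polymorphism) is computed.  Variant
   filters run in a fixed order — non-PASS, mappability-mask overlap,
   non-SNP/monomorphic, call rate < `min_gt_rate`, mean depth
   < `min_mean_depth`, FS > `max_fs`, MQ < `min_mq` — followed by removal
   of samples with missingness above `max_sample_missing`.  The order only
   determines which stage a multiply-failing variant is attributed to; a
   test asserts the surviving set equals the order-free conjunction of all
   rules.  Variant and sample passes are iterated to a fixed point (sample
   removal can in principle render a site monomorphic), which makes the
   operation idempotent.  "Genotyping quality ≥ 95%" is interpreted as the
   per-site successful-call rate across samples, kept explicit and
   configurable as `min_gt_rate`; an alternative reading (a per-genotype
   GQ summary) is not decidable from available descriptions, so the
   threshold name records the interpretation used.  Mean depth is read
   from INFO `DP_MEAN` when present, else derived from FORMAT `DP`.

2. **Region assignment.** A sample maps to its father's birth region when
   recorded, else its own — pushing the geographic snapshot one generation
   back and limiting the imprint of recent internal migration.  Exclusion
   reasons (no birthplace, foreign birth, excluded region) are evaluated
   in that order after QC sample removal; foreign birthplaces are a
   reserved code rather than free text because no gazetteer is bundled.
   The excluded-region list is explicit configuration (default: the single
   island region); no coverage-based rule is inferred.

3. **Tree building.** Variants with fewer than `min_mac` = 5 derived
   carriers are excluded (rare-lineage resolution is deliberately out of
   scope).  Every remaining pair is classified from the counts (n11, n10,
   n01) over samples genotyped at both sites: equivalent, nested,
   disjoint, conflicting (all three gamete patterns present), or ambiguous
   when fewer than `min_informative` (default 1) samples overlap.
   Conflicting variants are removed greedily — most conflicts first, ties
   by lower carrier count, then position, then name — a deterministic
   vertex-cover heuristic on the conflict graph.  Equivalence classes
   collapse into clades; a clade's carriers are the samples derived at a
   majority of its non-missing markers; the containment partial order is
   reduced to its Hasse diagram, which must be a tree (a clade with two
   incomparable ancestor candidates raises a structural error naming the
   variants).  Ambiguous pairs are left unordered, so a clade attaches at
   its lowest *certain* ancestor — conservative placement that never
   invents resolution.  Clade membership is cumulative: a sample carrying
   a child's markers descends from the parent's mutation even if missing
   there.  This pairwise-containment procedure is this package's own
   explicit formulation of the published-tool approach it stands in for;
   its exact tie-breaks are documented here rather than inherited.

4. **Sample assignment.** Each sample descends from the root to the
   deepest clade where it is derived at a majority of the clade's
   non-missing defining markers, requiring the same along every ancestor.
   An ancestor whose markers are all missing for the sample is passable,
   but the final assignment must carry positive evidence; samples with no
   evidence anywhere stay at the root.  The passable-ancestor rule exists
   because strict majority descent stalls a few percent of samples under
   realistic missingness even though a deeper clade identifies them
   unambiguously.

5. **Annotation.** Clades whose markers intersect a user-supplied alias
   table take the published label (disagreeing aliases: warning, first
   label lexicographically); the rest get systematic labels (parent label
   plus ordinal) and are flagged novel, with the novelty percentage
   reported to one decimal.

6. **Frequencies.** The country-wide frequency of haplogroup h is the
   census-weighted average of regional frequencies, F_h = Σ_r w_r f_{h,r},
   w_r = popsize_r / Σ popsize.  Regions sampled zero times have their
   census weight folded into the nearest adjacent sampled region by
   default (keeping Σ w_r = 1), or dropped with renormalisation.
   Within-major frequencies use the per-region carriers of the major
   haplogroup as denominators.  Point estimates only; no variance is
   attached to scaled frequencies.

7. **Enrichment.** Pearson χ² on the regions × {carrier, non-carrier}
   table against homogeneous proportions, df = R − 1, no continuity
   correction; small expected counts are handled by regional averaging
   (below-minimum regions fold into their nearest adjacent region, fewest
   hops, ties to the larger denominator), not by exact tests — a
   documented limitation.  The default minimum denominator is 5.
   Significance tiers: nominal (p < α) and Bonferroni-corrected
   (p < α / n_tests); n_tests comes from configuration because the
   published analysis used a divisor (96) differing from its selection
   count (103) for reasons not stated — neither is silently inferred.

8. **TMRCA.** rho = mean over clade members of the number of QC-passing
   variants (any carrier count) whose carriers all lie inside the clade,
   excluding the clade's own defining markers (they predate the MRCA);
   shared sub-clade mutations count once per tip.  TMRCA = rho × c with c
   a *required* years-per-mutation calibration (derivable as
   1 / (rate_per_bp_per_year × callable_bp)); no default is shipped
   because fabricating a rate would be worse than requiring one.  Sigma
   modes: `poisson_star` = sqrt(rho/n) (star genealogy), `saillard` =
   sqrt(Σ_v (k_v/n)²) with k_v the within-clade carrier count of variant v
   — the tree-weighted recursion expressed per variant, which needs the k
   vector that `count_derived` returns and reduces exactly to the star
   form when every mutation is private.  CI = (rho ± 1.96 σ) × c,
   truncated below at zero.  These are documented approximations; no
   claim of equivalence to any particular published CI construction is
   made.

9. **Autosomal structure.** PCA by SVD of column-standardised dosages
   (zero-variance loci dropped, missing dosages mean-imputed), with the
   deterministic sign convention that each component's largest-magnitude
   loading is positive.  LD pruning is a configuration hook left off for
   synthetic data.  PC-frequency correlation is a Pearson r across
   regional means with the t-transform p-value; zero-variance inputs are
   reported degenerate (r = 0, p = 1) rather than NaN.  Carrier contrasts
   use two-sided Mann-Whitney U (normal approximation with tie correction;
   exact for tiny groups).  Hudson F_ST per locus is
   [(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)] / [p1(1−p2) + p2(1−p1)],
   combined across loci as a ratio of averages (the standard low-bias
   choice over averaging ratios), with a block jackknife over contiguous
   locus blocks (default 500) for the standard error.

## The synthetic cohort generator

The generator's defaults encode the study conditions the analyses assume:
1833 men (1802 after exclusions) over 19 regions; sampling weights
proportional to census size times an eastern tilt (factor 0.6 + 1.8 ×
east-coordinate), emulating survey oversampling of the east; birth years
uniform on 1923–1979 (carried, analytically unused).  The genealogy is a
balanced tree (default depth 3, branching 2) whose leaves carry per-region
frequency vectors built from log-linear east-west clines.  Two leaves are
forced to strong opposite clines with major-lineage base shares, so the
realised country-wide structure lands near the dominant eastern lineage /
substantial western lineage split (~64% / ~25%) that motivates census
scaling; the remaining leaves get random clines.  Each non-root clade
carries 2–4 equivalent defining markers — haplogroup branches are
typically supported by several equivalent SNPs, and single-marker clades
would make samples missing that one call unplaceable — and a branch length
in expected private mutations per lineage (default uniform 0.5–1.5), with
per-sample private singletons drawn Poisson per path branch so rho-based
age recovery is analytically checkable.

Artifact plumbing mirrors the QC failure classes: decoy variants violating
each threshold (FS, MQ, depth, FILTER, mask overlap, call rate),
monomorphic sites, heterozygous "0/1" records among haploid calls, missing
calls, samples with > 75% missingness, and metadata corruption (missing
father's record → self-mapping; missing both → exclusion; foreign birth at
the observed survey rate ≈ 24/1833).  A relatives flag (default ≈ 8.4% of
samples) supports unrelated-subset reruns; relatedness itself is not
estimated.  Autosomal dosages are simulated with per-locus allele
frequencies shifting linearly along the east coordinate, giving a PC1 that
tracks geography and correlates with the Y clines; two-deme allele counts
for F_ST checks follow the Balding–Nichols model, whose drift parameter
equals the expected Hudson F_ST.

What the generator does **not** emulate: coalescent genealogy (no
Wright–Fisher dynamics, no variance in tree shape beyond the fixed
topology), recombination, sequence-level reads, within-region spatial
structure (regions are exchangeable bins), linkage among autosomal loci,
and haplotype-sharing ancestry profiles (a categorical label with a 0.5
ancestry-fraction threshold stands in for chromosome-painting profiles).
Passing tests therefore demonstrate correctness of the estimators and
procedures under the declared statistical structure, not robustness to
real-data pathologies such as reference bias, batch effects or cryptic
relatedness.

## Numerical and testing choices

Determinism throughout: one seeded generator per simulation call
(identical configuration ⇒ byte-identical VCF/TSV outputs); deterministic
tie-breaks (position ascending, then name) in conflict removal, class
ordering and child ordering; a fixed SVD sign convention.  Degenerate
inputs are explicit: empty VCFs yield zero ledgers, zero-carrier variants
define no clade, monomorphic-everywhere F_ST is flagged rather than NaN'd
silently, constant inputs to the correlation are flagged degenerate.

Test problem sizes are chosen to make the checks sharp but quick: 100
noiseless cohorts at n = 1802 for tree recovery, 2000 null draws for χ²
calibration, 200 for gradient power, 500 simulated clades for TMRCA bias
and coverage, 50 replicates at 20,000 loci for F_ST recovery; the
acceptance script uses 25 recovery cohorts.  The χ² power condition uses a
0.2 → 0.6 east-west cline — a 3-fold ratio at the frequency scale of the
major east-enriched sublineage (~42% cohort-wide).

## Known limitations

Ambiguity resolution in tree building is conservative rather than
exhaustive (no transitive closure search beyond lowest-certain-ancestor
placement); the χ² test relies on smoothing rather than exact small-sample
methods; scaled frequencies carry no uncertainty; the rho CI assumes
independent Poisson accumulation and is approximate for deeply structured
clades; the alias table is user-supplied and never fetched from external
databases.
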