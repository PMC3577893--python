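# Methods

This note documents the modeling assumptions, parameter defaults and
numerical conventions of `otulink`.  It is the contract the test suite
enforces.

## Distances (`otulink.distances`)

- **p-distance**: fraction of mismatching columns among columns where both
  sequences carry a residue (pairwise deletion of `-` and `?`).  A pair with
  zero shared residue columns has no defined distance and is an error naming
  the pair.  All distances are fractions in `[0, 1]`; interfaces quoting
  percentages divide by 100 before reaching the library.
- **Smith–Waterman similarity**: optimal local alignment under affine gap
  costs, reported as `100 × identities / alignment columns`.  Default scoring
  mirrors the common EMBOSS conventions for DNA: match `+5`, mismatch `−4`,
  gap open `10`, gap extend `0.5` (a gap of length `L` costs
  `open + L·extend`).  Gap characters are stripped before alignment.
- **Overlap filter**: a non-target record is kept when the number of columns
  simultaneously non-gap in it and in at least one target reaches the
  threshold.  Because "informative sites" is ambiguous, two countings are
  selectable: `shared` (default, every shared residue column) and `variable`
  (only columns with ≥ 2 distinct residues across the alignment).

## Clustering (`otulink.clustering`)

- **F-linkage agglomeration.** `link(i,j) ⇔ d(i,j) ≤ t`.  Starting from
  singletons, a cluster pair `(A, B)` is mergeable iff the linked fraction
  `f = |linked cross-pairs| / (|A|·|B|)` satisfies `f ≥ F` **and** `f > 0`.
  The pair with largest `f` merges first; ties break by smaller mean
  cross-distance, then by the lexicographically smallest member id.  The
  fraction comparison uses exact integer cross-multiplication, so the
  schedule is fully deterministic.  `F = 0` reproduces single linkage
  (connected components of the link graph); `F = 1` reproduces complete
  linkage (all within-cluster pairs linked) — both are asserted as oracles in
  the tests.
- **Agreement indices** are computed over pairs of reference-labeled elements
  only; unlabeled elements are ignored without penalty.  `rand` is the plain
  Rand index; `adjusted_rand` is the Hubert–Arabie chance-corrected version
  (delegated to scikit-learn); the default `modified_rand` (MRI) is
  `2·Rand − 1`, ranging over `[−1, 1]` with maximum 1.0 exactly when the
  restricted partitions coincide.  The MRI formula is a documented choice:
  the index family is configurable because published definitions vary.
- **Optimization** scans an `(F, t)` grid; the default threshold grid runs
  from 0 to the largest observed distance in steps of 0.0005 (0.05
  percentage points, matching the precision at which optimal thresholds are
  usually quoted).  Per `F` it reports the maximal agreement and the min /
  max / median of the thresholds attaining it.  The `ThresholdOptimizer`
  class wraps this scan in a fit-then-inspect shape
  (`ThresholdOptimizer(D, ref).fit(...).summary()`); the rest of the library
  uses plain functions because no other stage is a fitted model.
- **Identification**: all elements are clustered; a query inherits the
  species labels of the labeled references in its cluster (all of them when
  they conflict, flagged `ambiguous`) and is `novel` when its cluster has no
  labeled member.

## Parsimony (`otulink.parsimony`)

- Characters are integers with `−1` / `?` for missing; DNA columns are
  recoded as unordered characters with gaps treated as missing.  Unordered
  characters are scored with Fitch bitmask passes, ordered characters with
  Sankoff dynamic programming under linear step costs (`|i − j|`).  Missing
  states are free wildcards.
- **Search is exact**: stepwise-addition branch and bound over all unrooted
  binary topologies, pruning on the monotone partial score, returning every
  most-parsimonious topology in a canonical deterministic order.  The
  enumeration bound is 12 taxa — a package choice reflecting desk-scale
  problem sizes (at 13 taxa the 654,729,075 topologies are out of reach for
  an exact method); larger matrices are rejected with a pointer to heuristic
  tools.  The pipeline reduces larger datasets to one representative taxon
  per reference block before tree building.
- **DELTRAN branch lengths**: internal states are reconstructed per
  character by Sankoff dynamic programming; among co-optimal states the
  parent's state is preferred, then the smallest state index, in a preorder
  traversal with children in tree order — this delays transformations toward
  the tips.  Branch length is the integer change count per data partition;
  per-branch partition lengths sum to the tree score (a conservation law the
  tests assert).  Zero-length branches are retained, not collapsed.
- **Partitioned Bremer support**: for each internal split, the total Bremer
  value is the minimum score over all topologies lacking the split minus the
  global minimum.  Per-partition values are the partition-score differences
  on the best incompatible topology; when several incompatible topologies
  tie, the first in canonical enumeration order is used (a documented
  tie-break — partitioned values depend on it, their sum does not).  Values
  may be negative and always sum to the total.
- **Bootstrap**: characters resampled with replacement; a replicate supports
  a clade when the clade appears in the strict consensus of the replicate's
  most-parsimonious trees.  Bit-reproducible for a fixed seed.
- **Midpoint rooting** places the root halfway along the longest
  leaf-to-leaf path (total change counts as lengths); ties between equally
  long leaf pairs break by the lexicographically smallest sorted name pair.
  An all-zero-length tree roots on the edge above the first leaf, with a
  warning.

## Species boundaries (`otulink.boundaries`)

A branch is marked within-species iff some phenotype partition (default
`{macromorphology, physiology}`) contributes **strictly more** than the DNA
partition (`ITS`), either in Bremer support (`use_support`, internal
branches that carry support values) or in change counts (`use_lengths`, all
branches).  Marked branches — plus, by default, branches with zero total
change count (clonal variants) — are contracted; leaves connected through
contracted branches only form one species.  Marking more branches can only
merge species, never split them.  Path contraction (rather than clade
collapsing) is used because it handles zero-length terminals and
phenotype-dominated tips in a single rule.

## Coverage (`otulink.coverage`)

The default mode clusters the full dataset once and filters members by
deposition year, keeping cluster identities stable over time; re-clustering
each cumulative year subset is available as a flag.  Six statistics per
evaluation year: cumulative clusters, mean sequences per cluster, mean
distinct host genera / species per cluster, and mean clusters per host genus
/ species.  Sequences without a deposition year are excluded with a warning;
clusters whose members have no host annotation contribute 0 to the
host-per-cluster means, which is why those means can drop below 1.
Incomplete-year recoding (e.g. a half-covered final year stored as
`year − 0.5`) happens at metadata parse time, not here.

## Synthetic data (`otulink.simulate`)

The generator emulates a symbiont barcode survey on a star-of-stars
genealogy: a root sequence receives `ceil(d_between_min · L)` diagnostic
substitutions per species, then each sequence receives up to
`floor(d_within_max · L / 2)` private substitutions.  All mutated positions
are globally disjoint, so the configured bounds hold **exactly**: every
within-species p-distance is ≤ `d_within_max` and every between-species
p-distance is ≥ `2·ceil(d_between_min·L)/L ≥ d_between_min`.  Infeasible
combinations (more required positions than sites) are an error.  Phenotype
characters (default 30 ordered macromorphological with states 0–2, 8 binary
physiological) evolve on the same genealogy with separate per-edge change
rates between (`pheno_between_rate`, default 0.05) and within species
(`pheno_within_rate`, default 0.25), making phenotype faster within species
— the structure the boundary rule assumes.  Host genera are assigned per
species with probability `host_specificity` of the primary genus; host
annotations and species-level resolution are thinned by
`host_annotation_rate` and `host_species_resolution`.  Everything derives
from one integer seed.

Defaults (6 species × 5 sequences, 764-nt marker, within ≤ 1%, between
≥ 5%, 65% labeled, 3 host genera) mirror a small culture-collection survey.
**Scope and limits**: uniform substitution without indels (distances, not
alignments, are the modeling target), no rate heterogeneity, no coalescent
demography, star topology within species (clonal propagation).  The module
also provides `simulate_worked_examples()`, a bundle of hand-checkable
fixtures (chain distance matrix, small character matrices, a nine-culture
annotated example tree that yields six species, a six-sequence coverage
table) used throughout the tests and documentation.

## Pipeline and CLI

Stages `simulate → distances → parsimony → boundaries → optimize →
identify → coverage` communicate through named artifacts; a missing upstream
artifact raises an error naming the stage that produces it.  Configuration
is a plain INI file; every value can be overridden on the command line, and
the single seed recorded in `report.json` determines all randomness.

## Problem sizes

Intended scale: hundreds of sequences for distance/clustering stages
(the agglomeration maintains link counts incrementally and handles a
30-element matrix × 3 `F` values × ~750 thresholds in under a second),
≤ 12 taxa for exact parsimony and Bremer support, arbitrary metadata sizes
for coverage.  These bounds are package choices, asserted in the test
suite's timing-guarded acceptance tests.
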