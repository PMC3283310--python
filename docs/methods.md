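# Methods

This note documents the models and procedures coalphylo implements, the
defaults it chooses where the design was genuinely open, and what its
simulations do and do not show about real data.

## Trees, bipartitions, and supports

Trees are dendropy objects. All split-level operations view a tree as
unrooted: an internal edge induces the bipartition of the leaf set given by
the clade below it, keyed canonically by the side *not* containing the
lexicographically smallest leaf (so bipartition sets compare by plain set
equality, and a compatible split set's canonical sides form a laminar
family, from which `tree_from_bipartitions` builds the minimal displaying
tree directly).

Branch support is carried as numeric internal-node labels. Both [0, 1] and
percentage conventions occur in the wild; parsing auto-detects (any value
greater than 1 implies the percentage scale) and normalises to [0, 1].
`contract_low_support(t, 0.75)` removes internal edges with support
*strictly* below the threshold — an edge at exactly 75% survives — and
requires every internal edge to be annotated, erring rather than guessing.
Absent branch lengths mean "no length", never zero; operations needing
lengths raise.

## Accuracy: the missing-branch rate

`missing_branch_rate(true, est)` = |B(true) \ B(est)| / |B(true)| over
non-trivial bipartitions. The denominator is the *true* tree's internal
edge count (not n − 3), so a partially resolved reference is handled; for
the binary model trees of the simulations the two coincide. The rate is
kept as an exact rational and formatted as a percentage with one decimal
for reporting. Robinson–Foulds (`rf_distance`) is provided for fully
resolved comparisons; for binary pairs FN = RF / (2(n − 3)).

## Consensus methods

Majority consensus keeps splits with frequency strictly greater than 1/2
(such splits are pairwise compatible, so the tree always exists). Greedy
consensus then scans all remaining observed splits in decreasing frequency
and adds each one compatible with the accumulated set; its output therefore
always refines the majority tree. Frequency ties are ordered by (smaller
canonical side, then lexicographic side tuple) — the literature leaves this
open, and a deterministic rule makes runs reproducible.

## GLASS

Per-gene distance matrices are reduced element-wise by minimum and
clustered by single linkage (scipy); merge heights are divergence-time
estimates, so node depth is half the merge height and the merge order roots
the tree. Under the MSC with equal rates the minimum pairwise divergence
over many genes converges to the species divergence time, giving
statistical consistency on correct gene trees — a property the test suite
exercises directly. Note that the element-wise minimum is *not* robust to
multiplicative branch-length error: if gene trees share the species
topology but their lengths are independently perturbed, a perturbed path
can undercut a true divergence gap and reorder merges across short internal
branches. This is visible in the no-ILS construction check, where GLASS on
true (perturbed-length) gene trees is the one method that does not reliably
return the species topology — consistent with the very poor GLASS accuracy
reported in comparative studies.

## Reconciliation criteria

All three criteria score one gene tree against a rooted binary species tree
and sum over genes.

* **MDC.** For each internal species cluster C, k_C is the number of
  maximal gene-tree clades whose leaf sets lie inside C; the score is
  sum(k_C − 1) (the minimal number of extra lineages over all embeddings).
  For unrooted and/or partially resolved gene trees the score is the
  minimum over all rootings and all rooted binary refinements
  (`mdc_score_unrooted`, `MdcGeneScorer`), realising the constrained
  variant used when low-support edges have been contracted. Refinements are
  enumerated exhaustively when their count is within a configurable limit;
  beyond it, each polytomy is refined greedily guided by the candidate
  species tree (smallest species cluster that can hold two or more child
  blocks merges them caterpillar-style), making the score an upper bound in
  that regime. Inside the tree search the limit defaults to 64 to keep
  scoring affordable; correctness at small scale is defined against
  exhaustive lineage-history enumeration oracles in the test suite, not
  against the formulas.
* **Duplication / duplication–loss.** The LCA map M sends each gene node to
  the species LCA of its leaves. v is a duplication iff M(v) equals the
  image of one of its children; gene edge (v, u) implies
  d(M(u), M(v)) − 1 + [v is a duplication] losses, with d the edge-count
  distance. The LCA map minimises both counts over all valid event-labelled
  reconciliations (verified against map-enumeration oracles). Gene trees
  must be fully resolved; unrooted binary trees are scored at their best
  rooting, while unresolved trees are rejected for these criteria rather
  than silently refined.

## Species-tree search

Hill-climbing over rooted binary topologies. The start tree is the greedy
consensus of the gene trees, randomly refined to binary and randomly
rooted, plus a configurable number of random restarts; moves are rooted NNI
and optionally rooted SPR; the first strictly improving neighbourhood
optimum is taken, ties broken by fixed traversal order, everything
deterministic given the seed. On 5-taxon instances the NNI+SPR search
matches exhaustive enumeration over all 105 rooted trees on every random
instance tested; NNI alone can stall on plateaus of the duplication
criterion, which has many ties. `exhaustive_best_tree` provides the global
optimum for small n.

## Simulators

**Species trees** come from a birth–death process conditioned on the number
of extant tips (dendropy), are ultrametric by construction (asserted), with
default birth rate 1.0 and death rate 0.0 in time units.

**MSC gene trees.** Branch lengths are read in coalescent units (2N
generations), pair-coalescence rate 1: within a branch carrying k lineages,
waiting times are Exp(k(k−1)/2), truncated at the branch top; remaining
lineages coalesce above the root. One lineage is sampled per species. A
uniform `branch_scale` (default 0.05, the protocol's value for turning a
time-calibrated tree into a short-branched coalescent tree) controls ILS
intensity, and a single multiplier `coal_to_subst` (default 1.0) converts
gene-tree coalescent lengths to expected substitutions per site; both are
recorded in the dataset manifest. The simulator's 2-species mean divergence
and 3-taxon concordance probability 1 − (2/3)e^(−T) are checked against the
closed forms.

**No-ILS mode.** Every gene tree is topologically identical to the species
tree; half keep its branch lengths verbatim, half have each branch
multiplied by an independent positive mean-1 draw and are rescaled by one
constant to the original total treelength. The default family is lognormal
with mu = −sigma²/2 (mean exactly 1), sigma = 0.3 — moderate among-gene
rate variation; the family is pluggable.

**Sequences.** GTR rate matrix normalised to one expected substitution per
site per unit branch length; per-site continuous gamma rates (default
shape 1.0) drawn at the root and inherited, optional invariant-site
proportion; transition probabilities via the reversible eigendecomposition,
vectorised across sites. Indels follow a per-site Poisson process
(Gillespie over the evolving length; defaults 0.005 insertions and 0.005
deletions per site per substitution, truncated-geometric lengths p = 0.3,
max 10); insertions land uniformly between sites with content drawn from
the stationary frequencies, deletions clip at sequence ends. Homology is
tracked through a global column list, so the true alignment (with gaps) and
the unaligned sequences are both exact; no all-gap column can be emitted.
The substitution defaults are generic field-typical values chosen for
plausibility — they are explicit configuration, not estimates of any
particular empirical dataset. Root length defaults to 1000 sites.

## Gene-tree estimation (desk scale)

Heavyweight estimators (FastTree, RAxML, MrBayes, MAFFT) are deliberately
not reimplemented; their outputs can be imported as Newick. The
self-contained path is: logdet distance
d = −(1/4)[ln det F − (1/2) Σ ln(f_b g_b)] over pairwise-ungapped sites
(zero for identical sequences, consistent under general time-reversible
evolution; singular divergence matrices are capped at 10 with a warning,
small negatives clamped to zero), neighbor joining (scikit-bio, negative
branch estimates clamped), and column-resampling bootstrap supports
attached to the point tree's edges. `point_estimates` summarises a tree
sample by strict-majority consensus or by its modal topology (first
occurrence on ties), topology-only.

## Evaluation pipeline and statistics

`run_experiment` sweeps replicate datasets; per record it derives gene
trees per the method's source ("true" or NJ-with-bootstrap), applies the
point-estimate rule (full / 75%-contracted / sample-majority / sample-MAP),
runs the species method, and scores FN against the true species tree.
Method/data incompatibilities produce explicit error records rather than
aborting the sweep. Identical config and seed reproduce the table byte for
byte.

The Wilcoxon signed-rank test is two-sided; zero differences are dropped
before ranking (the classical convention; whether the original analyses
were one- or two-sided is not documented, so two-sided is reported). For
n ≤ 12 usable pairs the null is enumerated exactly over sign patterns with
average ranks for ties; above that, the normal approximation with
tie-corrected variance and a continuity correction is used (within 0.02 of
the exact value at n = 20 in tests). Bonferroni adjustment is
min(1, p·m) with m the number of comparisons in the invoked report.

## Problem sizes and what the tests show

The test suite and the acceptance script run at desk scale by design:
6–17 taxa, 2–32 genes, sequences of 300–1000 sites, 10–20 replicate
datasets, exhaustive oracles at n ≤ 6. These sizes are where exhaustive
enumeration is possible and where the qualitative phenomena (discord
growing as branches shorten, error shrinking with gene count, contraction
trading resolution for reliability) are already clearly measurable.

Passing tests therefore show correctness of the algorithms and simulators
under the stated models, not that any method is accurate on real data: the
simulator has one allele per species, no migration, duplication/loss-free
gene histories, equal rates across lineages for GLASS's assumptions, and
i.i.d. mean-1 length perturbation in no-ILS mode. Bootstrap proportions on
NJ trees are a more conservative support measure than SH-like values, so a
75% contraction threshold prunes harder here than in pipelines built on
FastTree; in gene-poor settings (8 genes or fewer) this measurably hurts
the greedy consensus, while at 12+ genes it is neutral within sampling
error — the regime the qualitative contraction check pins down.

## Known limitations

* Constraint-MDC scoring beyond the enumeration limit is a heuristic upper
  bound, not the exact optimum (the exact dynamic-programming formulation
  is out of scope).
* GLASS's rooting comes from the single-linkage merge order; no outgroup
  logic exists.
* The indel process's event rate uses the sequence length at each event
  (exact Gillespie), but insertions into a zero-length sequence are
  impossible, so a fully deleted lineage stays empty.
* `dup`/`duploss` on unresolved gene trees are rejected by design; refine
  or contract upstream.
* NEXUS and reticulate networks are not supported.
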