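"""Gene-tree/species-tree reconciliation criteria.

Three parsimony criteria for explaining gene-tree discord:

* **MDC (minimise deep coalescences).**  Embedding a gene tree into a
  species tree forces some gene lineages to persist past speciation events;
  each lineage beyond the first that exits a species-tree branch is an
  "extra lineage".  The minimum over embeddings has a closed form: for each
  internal cluster C of the species tree, count the maximal clades of the
  gene tree whose leaf sets lie inside C (call it k_C); the score is
  sum(k_C - 1).
* **Duplication / duplication-loss.**  Using the LCA reconciliation map M, a
  gene node v is a duplication when M(v) equals M(u) for one of its children
  u, and each gene edge (v, u) implies d(M(u), M(v)) - 1 + [v is a
  duplication] losses, where d is the edge-count distance in the species
  tree.  The LCA map minimises both the duplication count and the
  duplication+loss total.

For unrooted and/or partially resolved gene trees, the MDC score is the
minimum over all rootings and all rooted binary refinements
(:func:`mdc_score_unrooted`), which is how low-support polytomies are given
the benefit of the doubt.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Sequence

import dendropy

from .trees import (
    all_rootings,
    is_binary,
    leaf_labels,
    unrooted_copy,
)

__all__ = [
    "ReconciliationScore",
    "MdcGeneScorer",
    "lca_mapping",
    "mdc_score",
    "mdc_score_unrooted",
    "dup_loss_score",
]


@dataclass(frozen=True)
class ReconciliationScore:
    duplications: int
    losses: int
    extra_lineages: int

    @property
    def duploss(self) -> int:
        return self.duplications + self.losses


# ---------------------------------------------------------------------------
# Bitmask helpers (leaf sets as integers for speed)


def _leaf_index(tree: dendropy.Tree) -> dict:
    return {lbl: i for i, lbl in enumerate(sorted(leaf_labels(tree)))}


def _node_bits(tree: dendropy.Tree, index: dict) -> dict:
    bits = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            bits[nd] = 1 << index[nd.taxon.label]
        else:
            m = 0
            for c in nd.child_nodes():
                m |= bits[c]
            bits[nd] = m
    return bits


def _check_same_leaves(species: dendropy.Tree, gene: dendropy.Tree) -> None:
    if leaf_labels(species) != leaf_labels(gene):
        raise ValueError("gene and species trees are on different leaf sets")


# ---------------------------------------------------------------------------
# MDC


def _mdc_from_bits(species_clusters: Sequence[int], gene_root, gene_bits: dict) -> int:
    total = 0
    for cluster in species_clusters:
        # maximal gene clades inside `cluster`, found top-down
        k = 0
        stack = [gene_root]
        while stack:
            nd = stack.pop()
            b = gene_bits[nd]
            if b & ~cluster == 0:
                k += 1
            elif b & cluster:
                stack.extend(nd.child_nodes())
        total += k - 1
    return total


def _species_internal_clusters(species: dendropy.Tree, index: dict) -> list:
    bits = _node_bits(species, index)
    full = bits[species.seed_node]
    return [
        bits[nd]
        for nd in species.preorder_node_iter()
        if not nd.is_leaf() and bits[nd] != full
    ]


def mdc_score(species: dendropy.Tree, gene: dendropy.Tree) -> int:
    """Extra lineages implied by embedding a rooted gene tree in a rooted
    binary species tree (0 iff the gene tree displays every species cluster).

    The gene tree is scored as given; use :func:`mdc_score_unrooted` to score
    an unrooted or partially resolved gene tree via its best rooting and
    refinement.
    """
    _check_same_leaves(species, gene)
    if not gene.is_rooted:
        raise ValueError("gene tree must be rooted (see mdc_score_unrooted)")
    if not is_binary(species, rooted=True):
        raise ValueError("species tree must be rooted and binary")
    index = _leaf_index(species)
    clusters = _species_internal_clusters(species, index)
    gene_bits = _node_bits(gene, index)
    return _mdc_from_bits(clusters, gene.seed_node, gene_bits)


# -- refinements of polytomies ----------------------------------------------


def _n_refinements(tree: dendropy.Tree) -> int:
    total = 1
    for nd in tree.preorder_node_iter():
        d = len(nd.child_nodes())
        if d > 2:
            # number of rooted binary trees on d labelled tips: (2d-3)!!
            total *= math.prod(range(2 * d - 3, 0, -2))
    return total


def _binary_shapes(items):
    """All rooted binary groupings of `items` as nested tuples of indices."""
    if len(items) == 1:
        yield items[0]
        return
    if len(items) == 2:
        yield (items[0], items[1])
        return
    head, rest = items[-1], items[:-1]
    for shape in _binary_shapes(rest):
        yield from _graft(shape, head)


def _graft(shape, leaf):
    yield (shape, leaf)
    if isinstance(shape, tuple):
        a, b = shape
        for s in _graft(a, leaf):
            yield (s, b)
        for s in _graft(b, leaf):
            yield (a, s)


def _enumerate_refinement_clades(node, gene_bits):
    """Yield, for the subtree at `node`, every achievable multiset of clade
    bitmasks (as a tuple) of a rooted binary refinement."""
    if node.is_leaf():
        yield (gene_bits[node],)
        return
    kids = node.child_nodes()
    child_options = [list(_enumerate_refinement_clades(c, gene_bits)) for c in kids]

    def combos(i):
        if i == len(child_options):
            yield ()
            return
        for rest in combos(i + 1):
            for opt in child_options[i]:
                yield opt + rest

    child_masks = [gene_bits[c] for c in kids]
    for shape in _binary_shapes(list(range(len(kids)))):
        # clades introduced by resolving this polytomy (internal groupings)
        extra = []

        def mask_of(s):
            if isinstance(s, int):
                return child_masks[s]
            m = mask_of(s[0]) | mask_of(s[1])
            extra.append(m)
            return m

        root_mask = mask_of(shape)  # == gene_bits[node]; recorded in `extra`
        for below in combos(0):
            yield below + tuple(extra)


def _mdc_from_clade_masks(species_clusters, clade_masks, full) -> int:
    """MDC score given the clade bitmasks of a rooted gene tree (a laminar
    family including the singletons)."""
    masks = sorted(set(clade_masks), key=lambda m: -m.bit_count())
    total = 0
    for cluster in species_clusters:
        maximal = []
        for m in masks:  # descending size: ancestors precede descendants
            if m & ~cluster == 0 and not any(m & ~mx == 0 for mx in maximal):
                maximal.append(m)
        total += len(maximal) - 1
    return total


def _species_guided_refinement_masks(node, gene_bits, species_clusters_sorted):
    """Heuristic clade set: resolve each polytomy by repeatedly merging
    (caterpillar-style) the child blocks that fit inside the smallest species
    cluster able to hold two or more of them; leftovers are merged in input
    order.  Yields the clade bitmasks of one rooted binary refinement."""
    clades = []

    def merge_caterpillar(group):
        acc = group[0]
        for m in group[1:]:
            acc |= m
            clades.append(acc)
        return acc

    def visit(nd):
        if nd.is_leaf():
            m = gene_bits[nd]
            clades.append(m)
            return m
        masks = [visit(c) for c in nd.child_nodes()]
        while len(masks) > 2:
            for cluster in species_clusters_sorted:
                inside = [m for m in masks if m & ~cluster == 0]
                if 1 < len(inside) < len(masks):
                    for m in inside:
                        masks.remove(m)
                    masks.append(merge_caterpillar(inside))
                    break
            else:
                merged = merge_caterpillar(masks[:2])
                masks = masks[2:] + [merged]
        if len(masks) == 2:
            m = masks[0] | masks[1]
            clades.append(m)
        else:
            m = masks[0]
        return m

    visit(node)
    return tuple(clades)



#: refinement enumerations larger than this fall back to the guided heuristic
REFINEMENT_ENUMERATION_LIMIT = 5000


class MdcGeneScorer:
    """Prepared Constraint-MDC scorer for one gene tree.

    Enumerates the gene tree's rootings (and, when their number is within
    ``enumeration_limit``, all rooted binary refinements of each rooting) a
    single time; scoring against a candidate species tree is then a minimum
    over the precomputed clade structures.  Beyond the limit, a species-
    guided greedy refinement is built per rooting at scoring time, making
    the value an upper bound in that regime.  Reusing one scorer across many
    candidate species trees is how the tree search stays affordable.
    """

    def __init__(self, gene: dendropy.Tree, enumeration_limit: int = REFINEMENT_ENUMERATION_LIMIT):
        self.labels = sorted(leaf_labels(gene))
        self.index = {lbl: i for i, lbl in enumerate(self.labels)}
        self.full = (1 << len(self.labels)) - 1
        rootings = [gene] if gene.is_rooted else all_rootings(gene)
        exact = set()
        self._pending = []  # (rooted tree, node bitmasks) scored heuristically
        for rooted in rootings:
            bits = _node_bits(rooted, self.index)
            if _n_refinements(rooted) <= enumeration_limit:
                for masks in _enumerate_refinement_clades(rooted.seed_node, bits):
                    exact.add(tuple(sorted(masks)))
            else:
                self._pending.append((rooted, bits))
        self._exact = sorted(exact)

    def score(self, species: dendropy.Tree) -> int:
        if frozenset(self.labels) != leaf_labels(species):
            raise ValueError("gene and species trees are on different leaf sets")
        if not is_binary(species, rooted=True):
            raise ValueError("species tree must be rooted and binary")
        clusters = _species_internal_clusters(species, self.index)
        best = None
        for masks in self._exact:
            s = _mdc_from_clade_masks(clusters, masks, self.full)
            if best is None or s < best:
                best = s
            if best == 0:
                return 0
        if self._pending:
            sorted_clusters = sorted(clusters, key=lambda m: m.bit_count())
            for rooted, bits in self._pending:
                masks = _species_guided_refinement_masks(
                    rooted.seed_node, bits, sorted_clusters
                )
                s = _mdc_from_clade_masks(clusters, masks, self.full)
                if best is None or s < best:
                    best = s
                if best == 0:
                    return 0
        assert best is not None
        return best


def mdc_score_unrooted(
    species: dendropy.Tree,
    gene: dendropy.Tree,
    enumeration_limit: int = REFINEMENT_ENUMERATION_LIMIT,
) -> int:
    """MDC score of an unrooted, possibly unresolved gene tree: the minimum
    of :func:`mdc_score` over all rootings and rooted binary refinements.

    When the number of refinements exceeds ``enumeration_limit`` a
    species-tree-guided greedy refinement is used per rooting instead of
    exhaustive enumeration, making the value an upper bound in that regime.
    To score one gene tree against many species trees, build one
    :class:`MdcGeneScorer` instead.
    """
    _check_same_leaves(species, gene)
    return MdcGeneScorer(gene, enumeration_limit).score(species)


# ---------------------------------------------------------------------------
# LCA mapping and duplication/loss


def lca_mapping(gene: dendropy.Tree, species: dendropy.Tree) -> dict:
    """Map each gene node to the species-tree LCA of its leaf labels.

    Gene leaf labels must be a subset of the species labels; both trees must
    be rooted.  The returned dict is monotone: a child's image is at or below
    its parent's image.
    """
    if not gene.is_rooted or not species.is_rooted:
        raise ValueError("both trees must be rooted")
    g_leaves = leaf_labels(gene)
    s_leaves = leaf_labels(species)
    if not g_leaves <= s_leaves:
        raise ValueError("gene leaf labels are not a subset of species labels")
    index = {lbl: i for i, lbl in enumerate(sorted(s_leaves))}
    s_bits = _node_bits(species, index)
    postorder = list(species.postorder_node_iter())
    g_bits = _node_bits(gene, index)
    mapping = {}
    for gn in gene.postorder_node_iter():
        b = g_bits[gn]
        # first containing cluster in species postorder is the minimal one
        for sn in postorder:
            if b & ~s_bits[sn] == 0:
                mapping[gn] = sn
                break
    return mapping


def dup_loss_score(
    species: dendropy.Tree, gene: dendropy.Tree
) -> ReconciliationScore:
    """Duplications and losses of the LCA reconciliation of a rooted binary
    gene tree with a rooted binary species tree (plus the MDC extra-lineage
    count, so one call yields all three criteria)."""
    _check_same_leaves(species, gene)
    if not is_binary(gene, rooted=True) or not gene.is_rooted:
        raise ValueError("gene tree must be rooted and binary")
    if not is_binary(species, rooted=True) or not species.is_rooted:
        raise ValueError("species tree must be rooted and binary")
    mapping = lca_mapping(gene, species)
    depth = {}
    for nd in species.preorder_node_iter():
        depth[nd] = 0 if nd.parent_node is None else depth[nd.parent_node] + 1
    dups = 0
    losses = 0
    for gn in gene.preorder_internal_node_iter():
        kids = gn.child_nodes()
        is_dup = any(mapping[c] is mapping[gn] for c in kids)
        if is_dup:
            dups += 1
        for c in kids:
            d = depth[mapping[c]] - depth[mapping[gn]]
            losses += d - 1 + (1 if is_dup else 0)
    extra = mdc_score(species, gene)
    return ReconciliationScore(
        duplications=dups, losses=losses, extra_lineages=extra
    )
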