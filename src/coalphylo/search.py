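"""Heuristic species-tree search under MDC, duplication and dup-loss criteria.

Hill-climbing over rooted binary species-tree topologies with NNI moves
(optionally SPR), starting from the greedy consensus of the gene trees
randomly refined to binary, plus an optional number of random restarts.  The
criterion value of a candidate species tree is the sum of per-gene scores:
MDC accepts unrooted / partially resolved gene trees (scored through their
best rooting and refinement); the duplication-based criteria require fully
resolved gene trees, and unrooted ones are scored at their best rooting.

The search is deterministic given the config seed; ties are broken by first
candidate found in a fixed traversal order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy

from .consensus import greedy_consensus
from .reconcile import MdcGeneScorer, dup_loss_score, mdc_score
from .trees import (
    all_rootings,
    is_binary,
    leaf_labels,
    random_binary_tree,
    resolve_polytomies_random,
    tuple_to_tree,
)

__all__ = ["SearchConfig", "search_species_tree", "exhaustive_best_tree"]

_CRITERIA = ("mdc", "dup", "duploss")


@dataclass(frozen=True)
class SearchConfig:
    criterion: str = "mdc"
    moves: tuple = ("nni",)
    max_iterations: int = 100
    random_restarts: int = 2
    seed: int = 0
    # cap on exhaustive (rooting x refinement) enumeration per gene inside
    # the search; kept small so unresolved genes fall back to the guided
    # refinement heuristic rather than dominating the runtime
    refinement_limit: int = 64

    def __post_init__(self):
        if self.criterion not in _CRITERIA:
            raise ValueError(f"criterion must be one of {_CRITERIA}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.random_restarts < 0:
            raise ValueError("random_restarts must be >= 0")
        for m in self.moves:
            if m not in ("nni", "spr"):
                raise ValueError(f"unknown move type {m!r}")


# ---------------------------------------------------------------------------
# Per-gene scoring closures


def _gene_scorer(gene: dendropy.Tree, criterion: str, refinement_limit: int) -> Callable:
    """Return f(species_tree) -> int for one gene tree."""
    rooted_binary = gene.is_rooted and is_binary(gene, rooted=True)
    if criterion == "mdc":
        if rooted_binary:
            return lambda sp: mdc_score(sp, gene)
        return MdcGeneScorer(gene, enumeration_limit=refinement_limit).score
    # duplication-based criteria need fully resolved gene trees
    if gene.is_rooted:
        if not is_binary(gene, rooted=True):
            raise ValueError(
                f"{criterion} requires fully resolved gene trees; "
                "contract/refine before searching"
            )
        rootings = [gene]
    else:
        if not is_binary(gene, rooted=False):
            raise ValueError(
                f"{criterion} requires fully resolved gene trees; "
                "contract/refine before searching"
            )
        rootings = all_rootings(gene)

    if criterion == "dup":
        return lambda sp: min(dup_loss_score(sp, g).duplications for g in rootings)
    return lambda sp: min(dup_loss_score(sp, g).duploss for g in rootings)


def _total_scorer(
    gene_trees: Sequence[dendropy.Tree], criterion: str, refinement_limit: int
) -> Callable:
    scorers = [_gene_scorer(g, criterion, refinement_limit) for g in gene_trees]
    return lambda sp: sum(f(sp) for f in scorers)


# ---------------------------------------------------------------------------
# Topologies as nested tuples (fast move generation)


def _tree_to_shape(tree: dendropy.Tree):
    def rec(nd):
        if nd.is_leaf():
            return nd.taxon.label
        kids = [rec(c) for c in nd.child_nodes()]
        assert len(kids) == 2
        return _canon(kids[0], kids[1])

    return rec(tree.seed_node)


def _canon(a, b):
    return (a, b) if _min_leaf(a) <= _min_leaf(b) else (b, a)


def _min_leaf(s):
    if isinstance(s, str):
        return s
    return min(_min_leaf(s[0]), _min_leaf(s[1]))


def _nni_neighbors(shape):
    """All rooted-NNI neighbours of a rooted binary topology."""
    out = []

    def rec(s):
        if isinstance(s, str):
            return []
        a, b = s
        res = []
        if isinstance(a, tuple):
            a1, a2 = a
            res.append(_canon(_canon(b, a2), a1))
            res.append(_canon(_canon(a1, b), a2))
        if isinstance(b, tuple):
            b1, b2 = b
            res.append(_canon(b1, _canon(a, b2)))
            res.append(_canon(b2, _canon(b1, a)))
        for sub in rec(a):
            res.append(_canon(sub, b))
        for sub in rec(b):
            res.append(_canon(a, sub))
        return res

    return rec(shape)


def _spr_neighbors(shape):
    """All rooted-SPR neighbours: prune any proper subtree, regraft anywhere."""
    out = []
    for sub, rest in _prunings(shape):
        for g in _regrafts(rest, sub):
            out.append(g)
    return out


def _prunings(shape):
    """Yield (pruned_subtree, remainder) for every proper subtree."""
    if isinstance(shape, str):
        return
    a, b = shape
    yield a, b
    yield b, a
    for sub, rest in _prunings(a):
        yield sub, _canon(rest, b)
    for sub, rest in _prunings(b):
        yield sub, _canon(a, rest)


def _regrafts(shape, sub):
    yield _canon(shape, sub)
    if isinstance(shape, tuple):
        a, b = shape
        for g in _regrafts(a, sub):
            yield _canon(g, b)
        for g in _regrafts(b, sub):
            yield _canon(a, g)


# ---------------------------------------------------------------------------
# Search drivers


def _hill_climb(start_shape, score_of_shape, moves, max_iterations):
    current = start_shape
    current_score = score_of_shape(current)
    for _ in range(max_iterations):
        neighbors = []
        if "nni" in moves:
            neighbors.extend(_nni_neighbors(current))
        if "spr" in moves:
            neighbors.extend(_spr_neighbors(current))
        best, best_score = None, current_score
        seen = {current}
        for nb in neighbors:
            if nb in seen:
                continue
            seen.add(nb)
            s = score_of_shape(nb)
            if s < best_score:
                best, best_score = nb, s
        if best is None:
            break
        current, current_score = best, best_score
    return current, current_score


def search_species_tree(
    gene_trees: Sequence[dendropy.Tree], config: SearchConfig
):
    """Best rooted binary species tree found by hill-climbing.

    Returns ``(tree, score)``.  The start point is the greedy consensus of
    the gene trees, randomly refined to binary and randomly rooted;
    ``config.random_restarts`` additional random binary starting trees are
    explored and the best final score wins (first found on ties).
    """
    if not gene_trees:
        raise ValueError("empty gene tree list")
    labels = sorted(leaf_labels(gene_trees[0]))
    rng = random.Random(config.seed)
    total = _total_scorer(gene_trees, config.criterion, config.refinement_limit)

    cache: dict = {}

    def score_of_shape(shape):
        if shape not in cache:
            cache[shape] = total(tuple_to_tree(shape, rooted=True))
        return cache[shape]

    cons = greedy_consensus(gene_trees)
    cons_bin = resolve_polytomies_random(cons, rng)
    rooting = rng.choice(all_rootings(cons_bin))
    starts = [_tree_to_shape(rooting)]
    for _ in range(config.random_restarts):
        starts.append(_tree_to_shape(random_binary_tree(labels, rng, rooted=True)))

    best_shape, best_score = None, None
    for s in starts:
        shape, score = _hill_climb(
            s, score_of_shape, config.moves, config.max_iterations
        )
        if best_score is None or score < best_score:
            best_shape, best_score = shape, score
    return tuple_to_tree(best_shape, rooted=True), best_score


def exhaustive_best_tree(
    gene_trees: Sequence[dendropy.Tree], criterion: str, refinement_limit: int = 5000
):
    """Global optimum by scoring every rooted binary species-tree topology.

    Only sensible for small taxon sets ((2n-3)!! topologies).  Returns
    ``(tree, score)``; ties broken by enumeration order.
    """
    from .trees import enumerate_rooted_topologies

    if not gene_trees:
        raise ValueError("empty gene tree list")
    labels = sorted(leaf_labels(gene_trees[0]))
    total = _total_scorer(gene_trees, criterion, refinement_limit)
    best_tree, best_score = None, None
    for sp in enumerate_rooted_topologies(labels):
        s = total(sp)
        if best_score is None or s < best_score:
            best_tree, best_score = sp, s
    return best_tree, best_score
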