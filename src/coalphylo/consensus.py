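"""Majority and greedy (extended majority) consensus of gene trees.

The majority consensus displays exactly the splits appearing in strictly
more than half of the input trees (such splits are pairwise compatible, so
the tree always exists).  The greedy consensus then walks the remaining
observed splits in decreasing frequency, adding each one that is compatible
with the set accumulated so far; its output therefore always refines the
majority consensus.  Ties in frequency are broken deterministically by
(smaller canonical side first, then lexicographically), since the order is
otherwise unspecified in the literature.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import dendropy

from .trees import Bipartition, bipartitions, leaf_labels, is_compatible, tree_from_bipartitions

__all__ = ["split_frequencies", "majority_consensus", "greedy_consensus"]


def _common_leafset(trees: Sequence[dendropy.Tree]) -> frozenset:
    if not trees:
        raise ValueError("empty tree list")
    leaves = leaf_labels(trees[0])
    for t in trees[1:]:
        if leaf_labels(t) != leaves:
            raise ValueError("gene trees are on different leaf sets")
    return leaves


def split_frequencies(trees: Sequence[dendropy.Tree]) -> dict:
    """Frequency (fraction of input trees) of every observed non-trivial split."""
    leaves = _common_leafset(trees)
    counts: Counter = Counter()
    for t in trees:
        for b in bipartitions(t):
            counts[b] += 1
    n = len(trees)
    return {b: c / n for b, c in counts.items()}


def _greedy_order(freqs: dict) -> list:
    return sorted(
        freqs,
        key=lambda b: (-freqs[b], len(b.side), tuple(sorted(b.side))),
    )


def majority_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Tree displaying exactly the splits with frequency strictly > 1/2."""
    leaves = _common_leafset(trees)
    freqs = split_frequencies(trees)
    keep = [b for b in _greedy_order(freqs) if freqs[b] > 0.5]
    return tree_from_bipartitions(leaves, keep)


def greedy_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Extended-majority consensus: majority splits plus every further
    observed split, taken in decreasing frequency, that stays compatible."""
    leaves = _common_leafset(trees)
    freqs = split_frequencies(trees)
    accepted: list = []
    for b in _greedy_order(freqs):
        if is_compatible(b, accepted):
            accepted.append(b)
    return tree_from_bipartitions(leaves, accepted)
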