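"""Desk-scale gene-tree estimation: logdet distances, neighbor joining,
nonparametric bootstrap support, and point estimates from tree samples.

This is the self-contained stand-in for the heavyweight gene-tree estimators
(FastTree / RAxML / MrBayes) an assembled study would run externally: trees
produced by such tools can be read with :func:`coalphylo.parse_newick` and
fed to the same species-tree methods.  The internal path is
logdet distances -> neighbor joining, with column-resampling bootstrap for
branch support.

The logdet (paralinear) distance between taxa i and j is

    d(i, j) = -(1/4) [ ln det(F) - (1/2) sum_b ln(f_b g_b) ]

where F is the 4x4 relative divergence matrix over sites where neither
sequence is gapped or ambiguous (pairwise deletion), and f, g its marginals.
It is zero for identical sequences and consistent under general time-
reversible (indeed general Markov) evolution.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Sequence

import dendropy
import numpy as np
import skbio
from skbio import DistanceMatrix

from .alignment import Alignment
from .consensus import majority_consensus
from .trees import bipartitions, leaf_labels, parse_newick, set_edge_support, _clade_sets

__all__ = [
    "logdet_distance",
    "tree_path_distances",
    "nj_tree",
    "bootstrap_support",
    "point_estimates",
    "SATURATION_CAP",
]

#: distance assigned to saturated pairs (singular divergence matrix)
SATURATION_CAP = 10.0


def logdet_distance(aln: Alignment, saturation_cap: float = SATURATION_CAP) -> DistanceMatrix:
    """Pairwise logdet distances computed directly from an alignment.

    Sites with a gap or ambiguous base in either sequence of a pair are
    excluded for that pair only (pairwise deletion).  A pair whose divergence
    matrix is singular (saturation) is assigned ``saturation_cap`` and a
    warning is emitted.  Small negative estimates are clamped to zero.
    """
    codes = aln.as_codes()
    taxa = aln.taxa
    k = len(taxa)
    d = np.zeros((k, k))
    capped = []
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = codes[i], codes[j]
            valid = (xi >= 0) & (xj >= 0)
            n = int(valid.sum())
            if n == 0:
                raise ValueError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no comparable sites"
                )
            F = np.bincount(
                4 * xi[valid].astype(np.int64) + xj[valid], minlength=16
            ).reshape(4, 4) / n
            f = F.sum(axis=1)
            g = F.sum(axis=0)
            sign, ld = np.linalg.slogdet(F)
            if sign <= 0 or (f <= 0).any() or (g <= 0).any():
                dij = saturation_cap
                capped.append((taxa[i], taxa[j]))
            else:
                dij = -0.25 * (ld - 0.5 * (np.log(f).sum() + np.log(g).sum()))
                dij = max(dij, 0.0)
            d[i, j] = d[j, i] = dij
    if capped:
        warnings.warn(
            f"logdet saturation: {len(capped)} pair(s) capped at "
            f"{saturation_cap}: {capped[:5]}{'...' if len(capped) > 5 else ''}"
        )
    return DistanceMatrix(d, ids=taxa)


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distance matrix of a tree with branch lengths."""
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None and e.length is None:
            raise ValueError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    k = len(ids)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(d, ids=ids)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted neighbor-joining tree (negative branch lengths clamped to 0)."""
    if len(dm.ids) < 4:
        raise ValueError("neighbor joining requires at least 4 taxa")
    nj = skbio.tree.nj(dm, neg_as_zero=True)
    tree = parse_newick(str(nj))
    tree.is_rooted = False
    return tree


def bootstrap_support(
    aln: Alignment, replicates: int, rng: np.random.Generator
) -> dendropy.Tree:
    """NJ(logdet) point tree with bootstrap support on its internal edges.

    Support of each internal edge of the point tree is the fraction of
    column-resampled replicate trees displaying the same bipartition.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    point = nj_tree(logdet_distance(aln))
    counts: Counter = Counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(replicates):
            rep = nj_tree(logdet_distance(aln.resample_columns(rng)))
            for b in bipartitions(rep):
                counts[b] += 1
    below = _clade_sets(point)
    leaves = below[point.seed_node]
    from .trees import Bipartition

    for nd in point.preorder_node_iter():
        if nd is point.seed_node or nd.is_leaf():
            continue
        s = below[nd]
        if 1 < len(s) < len(leaves) - 1:
            b = Bipartition(s, leaves)
            set_edge_support(nd, counts[b] / replicates)
    return point


def point_estimates(sample: Sequence[dendropy.Tree], kind: str) -> dendropy.Tree:
    """Single-tree summary of a tree sample.

    ``kind="majority"``: the strict majority consensus (possibly unresolved).
    ``kind="map"``: the most frequent topology in the sample, ties broken by
    first occurrence.
    """
    if not sample:
        raise ValueError("empty tree sample")
    if kind == "majority":
        return majority_consensus(list(sample))
    if kind == "map":
        leaves = leaf_labels(sample[0])
        keys = []
        for t in sample:
            if leaf_labels(t) != leaves:
                raise ValueError("trees are on different leaf sets")
            keys.append(frozenset(bipartitions(t)))
        counts = Counter(keys)
        best = max(counts.values())
        for t, key in zip(sample, keys):
            if counts[key] == best:
                return t.clone(depth=1)
    raise ValueError("kind must be 'majority' or 'map'")
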