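"""GLASS: species trees by single-linkage clustering of minimum distances.

GLASS takes one distance matrix per gene, forms the element-wise minimum
D(i, j) = min_g d_g(i, j), and clusters taxa by single linkage on D (at each
step the two clusters with the smallest cross-pair distance merge).  Under
the multispecies coalescent with equal rates the minimum pairwise divergence
across many genes converges to the species divergence time, which makes the
method statistically consistent on correct gene trees.  The merge order
defines a rooted tree; merge heights are divergence-time estimates, so node
depth is half the merge height.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .trees import parse_newick

__all__ = ["min_distance_matrix", "glass_tree"]


def min_distance_matrix(matrices: Sequence[DistanceMatrix]) -> DistanceMatrix:
    """Element-wise minimum of per-gene distance matrices (common taxon set)."""
    if not matrices:
        raise ValueError("need at least one distance matrix")
    ids = sorted(matrices[0].ids)
    arrs = []
    for dm in matrices:
        if sorted(dm.ids) != ids:
            raise ValueError("distance matrices are on different taxon sets")
        a = dm.filter(ids).data
        if np.isnan(a).any():
            raise ValueError("NaN entries in distance matrix")
        if (a < 0).any():
            raise ValueError("negative entries in distance matrix")
        arrs.append(a)
    return DistanceMatrix(np.minimum.reduce(arrs), ids=ids)


def glass_tree(matrices: Sequence[DistanceMatrix]):
    """Rooted species tree from per-gene distance matrices.

    Single-linkage agglomeration on the element-wise minimum matrix; the
    returned dendropy tree is rooted, ultrametric, with node depths equal to
    half the merge heights.
    """
    dmin = min_distance_matrix(matrices)
    ids = list(dmin.ids)
    if len(ids) < 2:
        raise ValueError("need at least two taxa")
    Z = linkage(squareform(dmin.data, checks=False), method="single")
    # assemble newick bottom-up; cluster i < n is a leaf, else a merge row
    frags = {i: (ids[i], 0.0) for i in range(len(ids))}
    for k, (a, b, h, _) in enumerate(Z):
        depth = h / 2.0
        fa, da = frags.pop(int(a))
        fb, db = frags.pop(int(b))
        frag = f"({fa}:{max(depth - da, 0.0):.12g},{fb}:{max(depth - db, 0.0):.12g})"
        frags[len(ids) + k] = (frag, depth)
    (frag, _depth), = frags.values()
    tree = parse_newick(frag + ";")
    tree.is_rooted = True
    return tree
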