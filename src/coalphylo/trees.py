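"""Tree data model and bipartition machinery.

Trees are :class:`dendropy.Tree` objects throughout the package.  This module
adds the conventions the rest of the package relies on:

* Newick I/O in which internal-node labels carry branch support, normalised
  to the [0, 1] scale (percentage-scale inputs are auto-detected).
* Canonical bipartitions: an internal edge of the unrooted view of a tree is
  keyed by the split side that does *not* contain the lexicographically
  smallest leaf, so bipartition sets have plain set-equality semantics.
* Compatibility tests, consensus-style tree construction from a compatible
  split set, support-threshold contraction, and enumeration of all rootings
  of an unrooted tree.

All bipartition-level operations ignore the root: a rooted tree is viewed as
its unrooted topology first.  Branch lengths, where absent, mean "no length",
never zero.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "NewickParseError",
    "Bipartition",
    "parse_newick",
    "write_newick",
    "leaf_labels",
    "edge_support",
    "bipartitions",
    "clades",
    "contract_low_support",
    "all_rootings",
    "tree_from_bipartitions",
    "is_compatible",
    "same_topology",
    "is_binary",
    "random_binary_tree",
    "resolve_polytomies_random",
    "unrooted_copy",
    "enumerate_rooted_topologies",
    "enumerate_unrooted_topologies",
    "tuple_to_tree",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or validated."""


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy Tree.

    Internal-node labels that parse as numbers are interpreted as branch
    support values; values on a [0, 100] scale (any value > 1) are divided by
    100 so supports are always stored on [0, 1].  Multifurcations are
    preserved.  Raises :class:`NewickParseError` on malformed input (naming
    the character position when known) or duplicate leaf labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        col = getattr(exc, "col_num", None)
        where = f" at character offset {col}" if col is not None else ""
        raise NewickParseError(f"malformed Newick string{where}: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise NewickParseError("empty leaf label")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf label(s): {', '.join(dupes)}")
    _normalise_supports(tree)
    return tree


def _normalise_supports(tree: dendropy.Tree) -> None:
    vals = []
    for nd in tree.internal_nodes():
        v = _try_float(nd.label)
        if v is not None:
            vals.append(v)
    if not vals:
        return
    scale = 100.0 if any(v > 1.0 for v in vals) else 1.0
    for nd in tree.internal_nodes():
        v = _try_float(nd.label)
        if v is not None:
            v = v / scale
            if not 0.0 <= v <= 1.0:
                raise NewickParseError(f"support value {v!r} outside [0, 1]")
            nd.label = repr(v)


def _try_float(label) -> float | None:
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def edge_support(node: dendropy.Node) -> float | None:
    """Support of the edge above *node* (stored as a numeric node label)."""
    return _try_float(node.label)


def set_edge_support(node: dendropy.Node, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"support {value} outside [0, 1]")
    node.label = repr(float(value))


def write_newick(tree: dendropy.Tree, precision: int = 12) -> str:
    """Serialise a tree to one-line Newick (supports as internal labels)."""
    fmt = f".{precision}g"
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=fmt,
    )
    return s.strip()


# ---------------------------------------------------------------------------
# Bipartitions and clades


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of a leaf set induced by an internal edge.

    ``side`` is canonical: the half that does not contain the
    lexicographically smallest leaf.  Two Bipartition objects are equal iff
    they denote the same split of the same leaf set.
    """

    side: frozenset
    leaves: frozenset

    def __init__(self, side: Iterable[str], leaves: Iterable[str]):
        side = frozenset(side)
        leaves = frozenset(leaves)
        if not side or not leaves - side:
            raise ValueError("both sides of a bipartition must be non-empty")
        if not side <= leaves:
            raise ValueError("side is not a subset of the leaf set")
        if min(leaves) in side:
            side = leaves - side
        object.__setattr__(self, "side", side)
        object.__setattr__(self, "leaves", leaves)

    @property
    def other_side(self) -> frozenset:
        return self.leaves - self.side

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side), len(self.leaves) - len(self.side)) < 2

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        a = ",".join(sorted(self.side))
        b = ",".join(sorted(self.other_side))
        return f"Bipartition({a}|{b})"


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _clade_sets(tree: dendropy.Tree) -> dict:
    """Map each node to the frozenset of leaf labels below it (postorder)."""
    below = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
    return below


def clades(tree: dendropy.Tree, include_trivial: bool = False) -> set:
    """Rooted clusters (leaf sets of nodes).  A laminar family.

    With ``include_trivial`` the singletons and the full leaf set are
    included; otherwise only internal, proper clusters are returned.
    """
    below = _clade_sets(tree)
    full = below[tree.seed_node]
    out = set()
    for nd, s in below.items():
        if include_trivial or (1 < len(s) < len(full)):
            out.add(s)
    if include_trivial:
        out.add(full)
    return out


def bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions of the unrooted view of *tree*.

    One Bipartition per internal edge; for a fully resolved unrooted tree on
    n >= 4 leaves this has n - 3 elements.  The root is ignored (the two
    edges at a bifurcating root induce the same split, which is reported
    once).
    """
    below = _clade_sets(tree)
    leaves = below[tree.seed_node]
    out = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        s = below[nd]
        if 1 < len(s) < len(leaves) - 1:
            out.add(Bipartition(s, leaves))
    return out


def is_binary(tree: dendropy.Tree, rooted: bool | None = None) -> bool:
    """True if the tree is fully resolved (rooted: binary; unrooted: degree-3
    internals with a trifurcating seed node)."""
    if rooted is None:
        rooted = tree.is_rooted
    n_leaves = len(tree.leaf_nodes())
    if n_leaves <= 2:
        return True
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        k = len(nd.child_nodes())
        if nd is tree.seed_node:
            want = 2 if rooted else 3
            if n_leaves == 3 and not rooted:
                want = 3
            if k != want:
                return False
        elif k != 2:
            return False
    return True


# ---------------------------------------------------------------------------
# Support contraction


def contract_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Collapse internal edges whose support is strictly below *threshold*.

    "Below 75%" is strict: an edge with support exactly equal to the
    threshold is kept.  Every internal edge must carry a support value;
    otherwise a ValueError is raised.  Leaf edges are untouched.  Returns a
    new tree.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = tree.clone(depth=1)
    to_collapse = []
    for nd in out.preorder_node_iter():
        if nd is out.seed_node or nd.is_leaf():
            continue
        s = edge_support(nd)
        if s is None:
            raise ValueError(
                "internal edge without support value; contraction requires a "
                "fully annotated tree"
            )
        if s < threshold:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return out


# ---------------------------------------------------------------------------
# Rootings


def unrooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    """Copy of *tree* in unrooted form (a bifurcating root is collapsed)."""
    out = tree.clone(depth=1)
    out.is_rooted = False
    if len(out.seed_node.child_nodes()) == 2 and len(out.leaf_nodes()) > 2:
        out.collapse_basal_bifurcation()
    return out


def all_rootings(tree: dendropy.Tree) -> list:
    """All rooted versions of an unrooted tree, one per edge.

    The root is inserted on the midpoint of each edge (lengths, when present,
    are split evenly).  For an unrooted binary tree on n leaves this yields
    2n - 3 trees.
    """
    base = unrooted_copy(tree)
    below = _clade_sets(base)
    edge_keys = [
        below[e.head_node]
        for e in base.preorder_edge_iter()
        if e.tail_node is not None
    ]
    out = []
    for key in edge_keys:
        t = base.clone(depth=1)
        bl = _clade_sets(t)
        target = None
        for e in t.preorder_edge_iter():
            if e.tail_node is not None and bl[e.head_node] == key:
                target = e
                break
        assert target is not None
        length = target.length
        t.reroot_at_edge(target, update_bipartitions=False)
        t.is_rooted = True
        if length is not None:
            kids = t.seed_node.child_nodes()
            if len(kids) == 2:
                kids[0].edge.length = length / 2.0
                kids[1].edge.length = length / 2.0
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# Compatibility and construction from splits


def is_compatible(b: Bipartition, bs: Iterable[Bipartition]) -> bool:
    """True iff *b* together with *bs* can be displayed on a single tree.

    For splits of one common leaf set, pairwise compatibility implies joint
    compatibility, and two splits are compatible iff their canonical sides
    are nested or disjoint (both canonical sides exclude the smallest leaf,
    so the complement-complement intersection is never empty).
    """
    for other in bs:
        if other.leaves != b.leaves:
            raise ValueError("bipartitions refer to different leaf sets")
        a, c = b.side, other.side
        if not (a <= c or c <= a or not (a & c)):
            return False
    return True


def tree_from_bipartitions(
    leaves: Iterable[str], biparts: Iterable[Bipartition]
) -> dendropy.Tree:
    """Minimal unrooted tree displaying exactly the given compatible splits.

    An empty split set yields a star tree.  Raises ValueError if the input
    set is internally incompatible or refers to a different leaf set.
    """
    leaves = frozenset(leaves)
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves")
    biparts = list(biparts)
    for b in biparts:
        if b.leaves != leaves:
            raise ValueError("bipartition leaf set differs from supplied leaf set")
        if b.is_trivial:
            raise ValueError("trivial bipartition supplied")
    for i, b in enumerate(biparts):
        if not is_compatible(b, biparts[i + 1 :]):
            raise ValueError("incompatible bipartition set")
    # Canonical sides form a laminar family: build the rooted cluster tree.
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = False
    node_of = {}
    for lbl in sorted(leaves):
        nd = dendropy.Node()
        nd.taxon = taxon_ns.require_taxon(label=lbl)
        node_of[frozenset([lbl])] = nd
        tree.seed_node.add_child(nd)
    leafset_of = {nd: key for key, nd in node_of.items()}
    leafset_of[tree.seed_node] = leaves
    for side in sorted({b.side for b in biparts}, key=len):
        new = dendropy.Node()
        moved = [
            c for c in tree.seed_node.child_nodes() if leafset_of[c] <= side
        ]
        for c in moved:
            tree.seed_node.remove_child(c)
            new.add_child(c)
        tree.seed_node.add_child(new)
        leafset_of[new] = side
    return tree


# ---------------------------------------------------------------------------
# Topology comparison


def same_topology(
    t1: dendropy.Tree, t2: dendropy.Tree, rooted: bool = False
) -> bool:
    """Label-isomorphism of two trees.

    Unrooted comparison (default) compares non-trivial bipartition sets;
    rooted comparison compares rooted cluster sets.  Leaf sets must match for
    the trees to compare equal.
    """
    if leaf_labels(t1) != leaf_labels(t2):
        return False
    if rooted:
        return clades(t1, include_trivial=True) == clades(t2, include_trivial=True)
    return bipartitions(t1) == bipartitions(t2)


# ---------------------------------------------------------------------------
# Random and exhaustive topology generation (shared by search and oracles)


def tuple_to_tree(shape, rooted: bool = True) -> dendropy.Tree:
    """Build a tree from a nested-tuple topology, e.g. ``(('A','B'),'C')``."""

    def render(x) -> str:
        if isinstance(x, str):
            return x
        return "(" + ",".join(render(c) for c in x) + ")"

    t = parse_newick(render(shape) + ";")
    t.is_rooted = rooted
    if not rooted:
        t = unrooted_copy(t)
    return t


def random_binary_tree(
    labels: Sequence[str],
    rng: random.Random,
    rooted: bool = True,
    branch_length=None,
) -> dendropy.Tree:
    """Uniform-at-random binary topology by sequential random joins.

    ``branch_length`` may be a callable ``rng -> float`` used to draw every
    edge length; by default edges carry no lengths.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    items: list = list(labels)
    while len(items) > (2 if rooted else 3):
        i, j = sorted(rng.sample(range(len(items)), 2))
        b = items.pop(j)
        a = items.pop(i)
        items.append((a, b))
    t = tuple_to_tree(tuple(items), rooted=rooted)
    if branch_length is not None:
        for e in t.preorder_edge_iter():
            if e.tail_node is not None:
                e.length = branch_length(rng)
    return t


def resolve_polytomies_random(
    tree: dendropy.Tree, rng: random.Random
) -> dendropy.Tree:
    """Copy of *tree* with every polytomy resolved by random sequential joins."""
    out = tree.clone(depth=1)
    for nd in list(out.preorder_node_iter()):
        kids = nd.child_nodes()
        limit = 2
        while len(kids) > limit:
            i, j = sorted(rng.sample(range(len(kids)), 2))
            b = kids.pop(j)
            a = kids.pop(i)
            nd.remove_child(a)
            nd.remove_child(b)
            new = dendropy.Node()
            new.add_child(a)
            new.add_child(b)
            nd.add_child(new)
            kids.append(new)
    out.is_rooted = tree.is_rooted
    return out


def _rooted_shapes(labels: Sequence[str]) -> Iterator:
    """Yield all rooted binary topologies on *labels* as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    if len(labels) == 2:
        yield (labels[0], labels[1])
        return
    head, rest = labels[-1], labels[:-1]
    for shape in _rooted_shapes(rest):
        yield from _insert_leaf(shape, head)


def _insert_leaf(shape, leaf) -> Iterator:
    # attach above the whole tree (new root) ...
    yield (shape, leaf)
    # ... or inside either subtree
    if not isinstance(shape, str):
        a, b = shape
        for sub in _insert_leaf(a, leaf):
            yield (sub, b)
        for sub in _insert_leaf(b, leaf):
            yield (a, sub)


def enumerate_rooted_topologies(labels: Sequence[str]) -> Iterator[dendropy.Tree]:
    """All (2n-3)!! rooted binary topologies on *labels* (1, 1, 3, 15, 105...)."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    for shape in _rooted_shapes(labels):
        yield tuple_to_tree(shape, rooted=True)


def enumerate_unrooted_topologies(labels: Sequence[str]) -> Iterator[dendropy.Tree]:
    """All (2n-5)!! unrooted binary topologies on *labels*.

    Uses the bijection with rooted topologies on all labels but the first:
    the first label is attached at the (trifurcating) base.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    first, rest = labels[0], labels[1:]
    for shape in _rooted_shapes(rest):
        if isinstance(shape, str):
            t = tuple_to_tree((first, shape), rooted=False)
        else:
            a, b = shape
            t = tuple_to_tree((first, a, b), rooted=False)
        yield t
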