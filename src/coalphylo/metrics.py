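"""Tree-accuracy scoring: missing-branch (false negative) rate and RF distance.

The missing-branch rate is the proportion of internal branches of the *true*
tree whose bipartitions are absent from the estimated tree.  Unlike the
Robinson-Foulds distance it does not penalise an estimate for being
unresolved, which is why it is the right error measure when estimates may be
partially resolved; for a pair of fully resolved trees the two coincide up
to the 2(n-3) normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import dendropy

from .trees import bipartitions, leaf_labels

__all__ = ["ErrorScore", "missing_branch_rate", "rf_distance"]


@dataclass(frozen=True)
class ErrorScore:
    """Missing-branch error of an estimated tree against a reference.

    ``fn_rate`` is kept as an exact rational (missing / reference internal
    edges); ``float()`` or :meth:`as_percent` convert for reporting.
    """

    missing_count: int
    reference_internal_edges: int

    @property
    def fn_rate(self) -> Fraction:
        return Fraction(self.missing_count, self.reference_internal_edges)

    def __float__(self) -> float:
        return float(self.fn_rate)

    def as_percent(self, digits: int = 1) -> str:
        return f"{float(self.fn_rate) * 100:.{digits}f}%"


def _check_leafsets(t1: dendropy.Tree, t2: dendropy.Tree) -> None:
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("trees are on different leaf sets")


def missing_branch_rate(
    true_tree: dendropy.Tree, est_tree: dendropy.Tree
) -> ErrorScore:
    """Fraction of the true tree's internal bipartitions missing from the
    estimate.

    0.0 means the estimate displays every true internal branch (for a binary
    estimate: the trees are topologically identical); 1.0 means it displays
    none.  The estimate may be unresolved.  Raises if the leaf sets differ or
    the true tree has no internal edge (undefined denominator).
    """
    _check_leafsets(true_tree, est_tree)
    true_bp = bipartitions(true_tree)
    if not true_bp:
        raise ValueError(
            "true tree has no internal edges; missing-branch rate undefined"
        )
    est_bp = bipartitions(est_tree)
    missing = len(true_bp - est_bp)
    return ErrorScore(missing_count=missing, reference_internal_edges=len(true_bp))


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds (bipartition) distance: |B1 symmetric-difference B2|."""
    _check_leafsets(t1, t2)
    b1 = bipartitions(t1)
    b2 = bipartitions(t2)
    return len(b1 ^ b2)
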