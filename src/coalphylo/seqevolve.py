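"""Sequence evolution with substitutions and indels along a gene tree.

Substitutions follow a general time-reversible (GTR) rate matrix normalised
to one expected substitution per site per unit branch length, with optional
continuous gamma rate heterogeneity across sites (rates drawn per site at
the root and inherited) and a proportion of invariant sites.  Indels are a
Poisson process per site per unit branch length; insertion lengths follow a
truncated geometric distribution, inserted content is drawn from the
stationary base frequencies, insertion positions are uniform over the
sequence, and deletions clip at the sequence ends.

Homology is tracked exactly, so the simulator returns both the *true
alignment* (with gap characters marking indel history) and the unaligned
leaf sequences that an estimation pipeline would realign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import dendropy
import numpy as np

from .alignment import Alignment

__all__ = ["SubstitutionModel", "IndelModel", "simulate_sequences"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR(+Gamma+I) substitution model.

    ``exchangeabilities`` is the upper triangle (AC, AG, AT, CG, CT, GT) of
    the symmetric exchangeability matrix; ``gamma_shape`` of ``None`` means
    no rate heterogeneity.  The rate matrix is normalised so branch lengths
    are in expected substitutions per site.
    """

    exchangeabilities: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: Tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: Optional[float] = None
    invariant_proportion: float = 0.0

    def __post_init__(self):
        if len(self.exchangeabilities) != 6 or any(
            r < 0 for r in self.exchangeabilities
        ):
            raise ValueError("need 6 nonnegative exchangeabilities")
        if len(self.base_frequencies) != 4 or any(
            f <= 0 for f in self.base_frequencies
        ):
            raise ValueError("need 4 positive base frequencies")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-6:
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not 0.0 <= self.invariant_proportion < 1.0:
            raise ValueError("invariant proportion must lie in [0, 1)")

    @classmethod
    def jc(cls, gamma_shape: Optional[float] = None) -> "SubstitutionModel":
        """Jukes-Cantor preset: equal rates and frequencies."""
        return cls(gamma_shape=gamma_shape)

    @classmethod
    def default_gtr(cls) -> "SubstitutionModel":
        """A generic vertebrate-like GTR+Gamma parameterisation (used as the
        simulation default when no empirical estimates are supplied)."""
        return cls(
            exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
            base_frequencies=(0.30, 0.20, 0.20, 0.30),
            gamma_shape=1.0,
        )

    def rate_matrix(self) -> np.ndarray:
        """Normalised 4x4 GTR rate matrix Q (rows sum to 0, mean rate 1)."""
        pi = np.asarray(self.base_frequencies, dtype=float)
        pi = pi / pi.sum()
        r = np.zeros((4, 4))
        r[np.triu_indices(4, 1)] = self.exchangeabilities
        r = r + r.T
        Q = r * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def _eigen(self):
        """Reversible eigendecomposition: P(t) = A @ diag(exp(lam t)) @ C."""
        pi = np.asarray(self.base_frequencies, dtype=float)
        pi = pi / pi.sum()
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        A = V / sq[:, None]
        C = V.T * sq[None, :]
        return lam, A, C

    def draw_site_rates(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rates = (
            np.ones(n)
            if self.gamma_shape is None
            else rng.gamma(self.gamma_shape, 1.0 / self.gamma_shape, size=n)
        )
        if self.invariant_proportion > 0:
            rates[rng.random(n) < self.invariant_proportion] = 0.0
        return rates


@dataclass(frozen=True)
class IndelModel:
    """Indel process: events per site per unit branch length, with truncated
    geometric length distribution."""

    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    length_p: float = 0.3
    max_length: int = 10

    def __post_init__(self):
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise ValueError("indel rates must be nonnegative")
        if not 0.0 < self.length_p <= 1.0:
            raise ValueError("geometric parameter must lie in (0, 1]")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")

    @classmethod
    def none(cls) -> "IndelModel":
        return cls(0.0, 0.0)

    @classmethod
    def default(cls) -> "IndelModel":
        """Default gap process: 0.01 indels per site per substitution."""
        return cls(insertion_rate=0.005, deletion_rate=0.005)

    def length_probs(self) -> np.ndarray:
        k = np.arange(1, self.max_length + 1)
        p = self.length_p * (1 - self.length_p) ** (k - 1)
        return p / p.sum()


class _LinkedColumns:
    """Global homology-column order as a singly linked list."""

    HEAD = -1

    def __init__(self, n0: int):
        self.nxt = {}
        prev = self.HEAD
        for i in range(n0):
            self.nxt[prev] = i
            prev = i
        self.nxt[prev] = None
        self.counter = n0

    def new_block(self, after: int, k: int) -> np.ndarray:
        ids = np.arange(self.counter, self.counter + k, dtype=np.int64)
        self.counter += k
        tail = self.nxt[after]
        prev = after
        for i in ids:
            self.nxt[prev] = int(i)
            prev = int(i)
        self.nxt[prev] = tail
        return ids

    def order(self):
        out = []
        cur = self.nxt[self.HEAD]
        while cur is not None:
            out.append(cur)
            cur = self.nxt[cur]
        return out


def _substitute(bases, rates, t, eig, rng):
    if len(bases) == 0 or t == 0:
        return bases.copy()
    lam, A, C = eig
    et = np.exp(np.outer(t * rates, lam))  # (L, 4)
    probs = np.einsum("lk,lk,kj->lj", A[bases], et, C)
    np.clip(probs, 0.0, None, out=probs)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(len(bases))
    cum = np.cumsum(probs, axis=1)
    return (cum < u[:, None]).sum(axis=1).astype(np.int8)


def simulate_sequences(
    gene_tree: dendropy.Tree,
    subst: SubstitutionModel,
    indel: IndelModel,
    root_length: int,
    rng: np.random.Generator,
):
    """Evolve sequences down *gene_tree* (branch lengths = expected
    substitutions per site).

    Returns ``(true_alignment, unaligned)``: the gap-annotated true alignment
    over all leaves and the dict of gapless leaf sequences.
    """
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    for e in gene_tree.preorder_edge_iter():
        if e.tail_node is not None and e.length is None:
            raise ValueError("gene tree has missing branch lengths")

    pi = np.asarray(subst.base_frequencies, dtype=float)
    pi = pi / pi.sum()
    eig = subst._eigen()
    lenp = indel.length_probs()
    cols = _LinkedColumns(root_length)

    root_state = {
        "bases": rng.choice(4, size=root_length, p=pi).astype(np.int8),
        "ids": np.arange(root_length, dtype=np.int64),
        "rates": subst.draw_site_rates(root_length, rng),
    }

    def draw_len():
        return int(rng.choice(len(lenp), p=lenp)) + 1

    def evolve_branch(state, t):
        bases = _substitute(state["bases"], state["rates"], t, eig, rng)
        ids = state["ids"].copy()
        rates = state["rates"].copy()
        total_rate = indel.insertion_rate + indel.deletion_rate
        if total_rate > 0:
            elapsed = 0.0
            while len(bases) > 0:
                lam = total_rate * len(bases)
                elapsed += rng.exponential(1.0 / lam)
                if elapsed > t:
                    break
                if rng.random() < indel.insertion_rate / total_rate:
                    k = draw_len()
                    pos = int(rng.integers(0, len(bases) + 1))
                    after = int(ids[pos - 1]) if pos > 0 else _LinkedColumns.HEAD
                    new_ids = cols.new_block(after, k)
                    new_bases = rng.choice(4, size=k, p=pi).astype(np.int8)
                    new_rates = subst.draw_site_rates(k, rng)
                    bases = np.concatenate([bases[:pos], new_bases, bases[pos:]])
                    ids = np.concatenate([ids[:pos], new_ids, ids[pos:]])
                    rates = np.concatenate([rates[:pos], new_rates, rates[pos:]])
                else:
                    k = draw_len()
                    start = int(rng.integers(0, len(bases)))
                    stop = min(start + k, len(bases))
                    keep = np.ones(len(bases), dtype=bool)
                    keep[start:stop] = False
                    bases, ids, rates = bases[keep], ids[keep], rates[keep]
        return {"bases": bases, "ids": ids, "rates": rates}

    leaf_states = {}

    def walk(node, state):
        for child in node.child_nodes():
            cstate = evolve_branch(state, child.edge.length)
            if child.is_leaf():
                leaf_states[child.taxon.label] = cstate
            else:
                walk(child, cstate)

    root = gene_tree.seed_node
    if root.is_leaf():
        raise ValueError("gene tree must have at least one internal node")
    walk(root, root_state)

    # assemble the true alignment over columns present in at least one leaf
    present = set()
    for st in leaf_states.values():
        present.update(int(i) for i in st["ids"])
    order = [c for c in cols.order() if c in present]
    col_pos = {c: i for i, c in enumerate(order)}
    rows = {}
    for label, st in leaf_states.items():
        row = np.full(len(order), ord("-"), dtype=np.uint8)
        if len(st["ids"]):
            pos = np.array([col_pos[int(i)] for i in st["ids"]], dtype=np.int64)
            row[pos] = _BASES[st["bases"]]
        rows[label] = row.tobytes().decode("ascii")
    aln = Alignment(rows)
    return aln, aln.without_gaps()
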