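"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form scoring paths: MDC is
checked by enumerating all valid lineage histories (assignments of gene
coalescences to species branches), duplication/loss by enumerating all
monotone reconciliation maps, split compatibility by enumerating all binary
tree topologies, and the signed-rank test by enumerating sign patterns.
"""

from __future__ import annotations

import itertools

import numpy as np

from coalphylo.trees import (
    bipartitions,
    enumerate_unrooted_topologies,
    leaf_labels,
)


def _index(tree):
    return {lbl: i for i, lbl in enumerate(sorted(leaf_labels(tree)))}


def _masks(tree, idx):
    bits = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            bits[nd] = 1 << idx[nd.taxon.label]
        else:
            m = 0
            for c in nd.child_nodes():
                m |= bits[c]
            bits[nd] = m
    return bits


def _ancestors(tree):
    """node -> set of ancestors-or-self."""
    anc = {}
    for nd in tree.preorder_node_iter():
        anc[nd] = ({nd} if nd.parent_node is None
                   else anc[nd.parent_node] | {nd})
    return anc


def mdc_oracle(species, gene) -> int:
    """Minimum extra lineages over all valid lineage histories.

    A history assigns each gene coalescence to the species branch (the edge
    above a species node; the species root stands for the stem) in which it
    occurs, subject to: the branch's cluster contains the coalescence's
    leaves, and a parent coalescence is at or above its children's branches.
    Extra lineages on a branch = (gene edges crossing its top) - 1.
    """
    idx = _index(species)
    s_bits = _masks(species, idx)
    g_bits = _masks(gene, idx)
    anc = _ancestors(species)
    s_leaf = {nd.taxon.label: nd for nd in species.leaf_node_iter()}
    gene_internal = [nd for nd in gene.postorder_node_iter() if not nd.is_leaf()]
    candidates = {
        v: [x for x in species.preorder_node_iter()
            if g_bits[v] & ~s_bits[x] == 0]
        for v in gene_internal
    }
    non_root = [x for x in species.preorder_node_iter() if x.parent_node is not None]
    gene_edges = [
        (p, c) for p in gene.preorder_node_iter() for c in p.child_nodes()
    ]

    best = [None]

    def location(nd, assign):
        if nd.is_leaf():
            return s_leaf[nd.taxon.label]
        return assign[nd]

    desc_or_self = {x: set() for x in species.preorder_node_iter()}
    for x in species.preorder_node_iter():
        for a in anc[x]:
            desc_or_self[a].add(x)

    def full_score(assign):
        total = 0
        for x in non_root:
            k = 0
            for p, c in gene_edges:
                loc_c = location(c, assign)
                loc_p = assign[p]
                if loc_c in desc_or_self[x] and loc_p not in desc_or_self[x]:
                    k += 1
            total += k - 1
        return total

    def rec(i, assign):
        if i == len(gene_internal):
            s = full_score(assign)
            if best[0] is None or s < best[0]:
                best[0] = s
            return
        v = gene_internal[i]
        for x in candidates[v]:
            ok = True
            for c in v.child_nodes():
                if not c.is_leaf() and x not in anc[assign[c]]:
                    ok = False
                    break
            if ok:
                assign[v] = x
                rec(i + 1, assign)
                del assign[v]

    rec(0, {})
    assert best[0] is not None
    return best[0]


def duploss_oracle(species, gene):
    """Minimum duplications and minimum duplications+losses over all
    monotone reconciliation maps (event-labelled embeddings)."""
    anc = _ancestors(species)
    idx = _index(species)
    s_bits = _masks(species, idx)
    postorder_s = list(species.postorder_node_iter())

    def lca_of(a, b):
        common = anc[a] & anc[b]
        return max(common, key=lambda x: len(anc[x]))  # deepest common ancestor

    depth = {x: len(anc[x]) - 1 for x in species.preorder_node_iter()}
    s_leaf = {nd.taxon.label: nd for nd in species.leaf_node_iter()}
    gene_internal = [nd for nd in gene.postorder_node_iter() if not nd.is_leaf()]
    best_dup = [None]
    best_dl = [None]

    def mapped(nd, assign):
        return s_leaf[nd.taxon.label] if nd.is_leaf() else assign[nd]

    def evaluate(assign):
        dups = 0
        losses = 0
        for v in gene_internal:
            kids = v.child_nodes()
            mv = assign[v]
            ca, cb = (mapped(c, assign) for c in kids)
            # a speciation requires mapping exactly to the children's LCA,
            # with the children descending into its two distinct sides
            is_dup = (mv is ca) or (mv is cb) or (mv is not lca_of(ca, cb))
            if is_dup:
                dups += 1
            for c in kids:
                d = depth[mapped(c, assign)] - depth[mv]
                losses += d - 1 + (1 if is_dup else 0)
        if best_dup[0] is None or dups < best_dup[0]:
            best_dup[0] = dups
        if best_dl[0] is None or dups + losses < best_dl[0]:
            best_dl[0] = dups + losses

    def rec(i, assign):
        if i == len(gene_internal):
            evaluate(assign)
            return
        v = gene_internal[i]
        a, b = (mapped(c, assign) for c in v.child_nodes())
        low = lca_of(a, b)
        for x in anc[low]:
            assign[v] = x
            rec(i + 1, assign)
        del assign[v]

    rec(0, {})
    return best_dup[0], best_dl[0]


def compatibility_oracle(split, others, labels) -> bool:
    """True iff some binary tree on *labels* displays {split} + others."""
    wanted = {split, *others}
    for t in enumerate_unrooted_topologies(sorted(labels)):
        if wanted <= bipartitions(t):
            return True
    return False


def wilcoxon_enumeration(diffs) -> float:
    """Two-sided exact signed-rank p-value by explicit 2^n enumeration."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        stats.append(w)
    stats = np.asarray(stats)
    p_le = (stats <= w_obs + 1e-9).mean()
    p_ge = (stats >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))
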