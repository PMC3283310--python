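"""Synthetic study data: species trees, coalescent gene trees, perturbed
gene trees, and full dataset bundles.

Two experimental regimes are generated:

* **ILS mode** — a birth-death species tree is uniformly scaled (default
  factor 0.05) so its branches are short in coalescent units, and gene trees
  are simulated under the multispecies coalescent within it: one sampled
  lineage per species, lineages coalescing backwards in time at rate
  k(k-1)/2 within each species-tree branch (branch lengths in units of 2N
  generations), with remaining lineages coalescing above the root.
* **no-ILS mode** — every gene tree is topologically identical to the
  species tree; half the genes use its branch lengths verbatim, half have
  every branch multiplied by an independent mean-1 lognormal factor and are
  rescaled back to the original total treelength, modelling among-gene rate
  variation without any true discord.

Sequences of a configurable root length (default 1000) are then evolved
along each gene tree under GTR+Gamma with indels
(:mod:`coalphylo.seqevolve`).  Everything is reproducible from the config
seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .alignment import Alignment
from .seqevolve import IndelModel, SubstitutionModel, simulate_sequences
from .trees import parse_newick, write_newick

__all__ = [
    "generate_species_tree",
    "scale_branches",
    "perturb_branch_lengths",
    "simulate_msc_gene_tree",
    "ExperimentConfig",
    "DatasetBundle",
    "generate_dataset",
    "write_dataset",
]


def generate_species_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    rng: Optional[random.Random] = None,
    seed: Optional[int] = None,
) -> dendropy.Tree:
    """Ultrametric rooted binary species tree under a birth-death process,
    conditioned on the number of extant tips (extinct lineages pruned)."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth rate > death rate >= 0")
    if rng is None:
        rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    tree.is_rooted = True
    tree.seed_node.edge.length = None  # no stem branch
    depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
    if max(depths) - min(depths) > 1e-6 * max(depths):
        raise AssertionError("birth-death tree is not ultrametric")
    return tree


def _iter_length_edges(tree: dendropy.Tree):
    for e in tree.preorder_edge_iter():
        if e.tail_node is None:
            if e.length is not None:
                yield e
        else:
            yield e


def scale_branches(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    """Copy of *tree* with every branch length multiplied by *factor*."""
    if not factor > 0:
        raise ValueError("factor must be positive")
    out = tree.clone(depth=1)
    for e in _iter_length_edges(out):
        if e.length is None:
            raise ValueError("tree has missing branch lengths")
        e.length = e.length * factor
    return out


def lognormal_mean_one(sigma: float) -> Callable[[random.Random], float]:
    """Positive multiplier distribution with expected value exactly 1
    (lognormal with mu = -sigma^2/2)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    mu = -(sigma**2) / 2.0

    def draw(rng: random.Random) -> float:
        return math.exp(rng.gauss(mu, sigma))

    return draw


def perturb_branch_lengths(
    tree: dendropy.Tree,
    rng: random.Random,
    sigma: float = 0.3,
    distribution: Optional[Callable[[random.Random], float]] = None,
) -> dendropy.Tree:
    """Multiply each branch by an independent mean-1 positive draw, then
    rescale all branches by one constant so the total treelength is exactly
    preserved.  Topology unchanged."""
    if distribution is None:
        distribution = lognormal_mean_one(sigma)
    out = tree.clone(depth=1)
    edges = list(_iter_length_edges(out))
    if any(e.length is None for e in edges):
        raise ValueError("tree has missing branch lengths")
    total_before = sum(e.length for e in edges)
    for e in edges:
        m = distribution(rng)
        while m <= 0:  # guard against a degenerate user-supplied family
            m = distribution(rng)
        e.length = e.length * m
    total_after = sum(e.length for e in edges)
    if total_after > 0:
        c = total_before / total_after
        for e in edges:
            e.length = e.length * c
    return out


def simulate_msc_gene_tree(
    species: dendropy.Tree, rng: random.Random
) -> dendropy.Tree:
    """One multispecies-coalescent gene tree within *species*.

    One lineage is sampled per species; within each species-tree branch
    carrying k lineages, coalescences occur after Exp(k(k-1)/2) waiting
    times (branch lengths in coalescent units of 2N generations), truncated
    at the branch top; surviving lineages coalesce freely above the root.
    Returns a rooted binary tree with coalescent-unit branch lengths.
    """
    for e in species.preorder_edge_iter():
        if e.tail_node is not None and e.length is None:
            raise ValueError("species tree has missing branch lengths")
    # node ages, measured back from the latest tip
    depth = {}
    for nd in species.preorder_node_iter():
        depth[nd] = (
            0.0
            if nd.parent_node is None
            else depth[nd.parent_node] + nd.edge.length
        )
    height = max(depth[lf] for lf in species.leaf_node_iter())
    age = {nd: height - d for nd, d in depth.items()}

    def coalesce(lineages, start, stop):
        """lineages: list of (newick_fragment, age); coalesce on [start, stop)."""
        t = start
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.expovariate(k * (k - 1) / 2.0)
            if t >= stop:
                break
            i, j = rng.sample(range(k), 2)
            (fa, aa), (fb, ab) = lineages[i], lineages[j]
            merged = f"({fa}:{t - aa:.12g},{fb}:{t - ab:.12g})"
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append((merged, t))
        return lineages

    def process(node):
        if node.is_leaf():
            lineages = [(node.taxon.label, age[node])]
        else:
            lineages = []
            for c in node.child_nodes():
                lineages.extend(process(c))
        if node.parent_node is None:
            return coalesce(lineages, age[node], math.inf)
        return coalesce(lineages, age[node], age[node.parent_node])

    (frag, _a), = process(species.seed_node)
    gene = parse_newick(frag + ";")
    gene.is_rooted = True
    return gene


# ---------------------------------------------------------------------------
# Dataset bundles


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one simulated multi-gene dataset.

    ``mode="ils"``: the species tree is scaled by ``branch_scale`` into
    coalescent units and gene trees are MSC draws, converted to substitution
    units with ``coal_to_subst``.  ``mode="noils"``: gene trees share the
    species topology; half keep its lengths, half are perturbed
    (mean-1 lognormal, ``perturb_sigma``) and rescaled to equal treelength.
    """

    n_taxa: int = 20
    n_genes: int = 25
    mode: str = "ils"
    root_length: int = 1000
    branch_scale: float = 0.05
    coal_to_subst: float = 1.0
    birth_rate: float = 1.0
    death_rate: float = 0.0
    perturb_sigma: float = 0.3
    subst_model: SubstitutionModel = field(
        default_factory=SubstitutionModel.default_gtr
    )
    indel_model: IndelModel = field(default_factory=IndelModel.default)
    species_tree_newick: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.mode not in ("ils", "noils"):
            raise ValueError("mode must be 'ils' or 'noils'")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if not self.branch_scale > 0 or not self.coal_to_subst > 0:
            raise ValueError("scale factors must be positive")


@dataclass
class DatasetBundle:
    """Everything one simulated dataset comprises."""

    config: ExperimentConfig
    species_tree: dendropy.Tree  # original (time/substitution) units
    coalescent_species_tree: Optional[dendropy.Tree]  # ILS mode only
    gene_trees: List[dendropy.Tree]  # true gene trees (rooted)
    sequence_trees: List[dendropy.Tree]  # substitution-unit trees used for sequences
    alignments: List[Alignment]  # true alignments (with gaps)
    sequences: List[dict]  # unaligned leaf sequences per gene


def generate_dataset(config: ExperimentConfig) -> DatasetBundle:
    """Simulate one dataset bundle, fully reproducible from ``config.seed``."""
    rng = random.Random(config.seed)
    nprng = np.random.default_rng([config.seed, 0x5EED])

    if config.species_tree_newick is not None:
        species = parse_newick(config.species_tree_newick)
        species.is_rooted = True
    else:
        species = generate_species_tree(
            config.n_taxa, config.birth_rate, config.death_rate, rng=rng
        )

    coalescent_tree = None
    if config.mode == "ils":
        coalescent_tree = scale_branches(species, config.branch_scale)
        gene_trees = [
            simulate_msc_gene_tree(coalescent_tree, rng)
            for _ in range(config.n_genes)
        ]
        seq_trees = [
            scale_branches(g, config.coal_to_subst) for g in gene_trees
        ]
    else:
        n_plain = config.n_genes - config.n_genes // 2
        gene_trees = []
        for i in range(config.n_genes):
            if i < n_plain:
                g = species.clone(depth=1)
            else:
                g = perturb_branch_lengths(species, rng, sigma=config.perturb_sigma)
            g.is_rooted = True
            gene_trees.append(g)
        seq_trees = [g.clone(depth=1) for g in gene_trees]

    alignments, sequences = [], []
    for st in seq_trees:
        aln, raw = simulate_sequences(
            st, config.subst_model, config.indel_model, config.root_length, nprng
        )
        alignments.append(aln)
        sequences.append(raw)

    return DatasetBundle(
        config=config,
        species_tree=species,
        coalescent_species_tree=coalescent_tree,
        gene_trees=gene_trees,
        sequence_trees=seq_trees,
        alignments=alignments,
        sequences=sequences,
    )


def write_dataset(bundle: DatasetBundle, outdir) -> None:
    """Write a bundle as plain-text files (Newick, FASTA, JSON manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "species.nwk").write_text(write_newick(bundle.species_tree) + "\n")
    with open(outdir / "genes.nwk", "w") as fh:
        for g in bundle.gene_trees:
            fh.write(write_newick(g) + "\n")
    for i, aln in enumerate(bundle.alignments, start=1):
        aln.to_fasta(outdir / f"gene{i:03d}.true.fasta")
        with open(outdir / f"gene{i:03d}.fasta", "w") as fh:
            for name, seq in bundle.sequences[i - 1].items():
                fh.write(f">{name}\n{seq}\n")
    cfg = dataclasses.asdict(bundle.config)
    (outdir / "manifest.json").write_text(json.dumps(cfg, indent=2, default=str))
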