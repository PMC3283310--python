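"""Simulate a multi-gene dataset with incomplete lineage sorting.

Builds a birth-death species tree, scales its branches into coalescent
units so that deep coalescence is common, draws gene trees under the
multispecies coalescent, and evolves gapped sequences along them.
"""

import coalphylo as cp

config = cp.ExperimentConfig(
    n_taxa=10,
    n_genes=8,
    mode="ils",
    branch_scale=0.3,   # coalescent-unit scaling; smaller => more discord
    root_length=500,
    seed=42,
)
bundle = cp.generate_dataset(config)

print("species tree:", cp.write_newick(bundle.species_tree))
print(f"{len(bundle.gene_trees)} gene trees; per-gene FN rate vs species tree:")
for i, gene in enumerate(bundle.gene_trees, 1):
    fn = cp.missing_branch_rate(bundle.species_tree, gene)
    print(f"  gene {i}: {fn.as_percent()}  ({fn.missing_count} of "
          f"{fn.reference_internal_edges} species branches missing)")
aln = bundle.alignments[0]
print(f"first alignment: {len(aln)} taxa x {aln.length} columns "
      f"(root length {config.root_length}; indels add/remove columns)")

# A nonzero per-gene FN rate here is *true* gene-tree/species-tree discord
# caused by deep coalescence, not estimation error: these are the simulated
# gene trees themselves.
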