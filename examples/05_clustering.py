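"""Two-way hierarchical clustering of DEG expression profiles.

With planted effects and modest noise the three replicates of each design
cell should sit together in the sample dendrogram — the visual reliability
check of the experimental design.
"""

import lowphos as lp

spec = lp.default_scenario(rng_seed=2, n_genes=400)
matrix, sheet, truth = lp.simulate_dataset(spec)

degs = sorted(set(truth.treatment_degs["gene_id"]) | set(truth.patterns["gene_id"]))
sub = matrix.subset_genes(degs)
print(f"clustering {len(degs)} planted DEGs across {len(sub.sample_ids)} arrays")

sample_dist = lp.distance_matrix(sub, "samples", "euclidean")
sample_tree = lp.hierarchical_cluster(sample_dist, "average")
frac = lp.replicate_clade_fraction(sample_tree, sheet)
print(f"replicate triplets forming clean clades: {frac:.0%} of the 8 cells")

gene_dist = lp.distance_matrix(sub, "genes", "correlation")
gene_tree = lp.hierarchical_cluster(gene_dist, "average")
print(f"gene dendrogram root height (correlation distance): {gene_tree.height:.3f}")

newick = lp.to_newick(sample_tree)
print(f"sample dendrogram as Newick ({len(newick)} chars):")
print(newick[:100] + "...")
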