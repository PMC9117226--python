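"""Intergenic geometry: neighbor gaps, length classes, pair orientations.

Builds a small synthetic genome, computes each gene's upstream (x) and
downstream (y) gaps to its nearest protein-coding neighbors, and
enumerates adjacent gene pairs with their shared intergenic intervals.
"""

from intergenic import (
    SyntheticConfig,
    build_neighbor_contexts,
    enumerate_gene_pairs,
    generate_bundle,
)

bundle = generate_bundle(SyntheticConfig(
    seed=42, n_chromosomes=2, genes_per_chromosome=1000))
contexts = build_neighbor_contexts(bundle.universe)
pairs = enumerate_gene_pairs(bundle.universe)

print(f"genes: {len(bundle.universe)}, "
      f"genes with a neighbor context: {len(contexts)}")
print("\nfirst contexts (x + y = intergenic length):")
print(contexts.head(4).to_string(index=False))

print("\nintergenic length classes "
      "(EID > 500 kb, extended > 100 kb, short < 10 kb):")
print(contexts["length_class"].value_counts().to_string())

print("\nadjacent-pair orientations "
      "(HH divergent, TH/HT tandem, TT convergent):")
print(pairs["orientation"].value_counts().to_string())
print(f"\nmedian shared intergenic interval: "
      f"{pairs['shared_length_bp'].median() / 1000:.1f} kb")
# EID genes are the long-intergenic tail that the neural analyses focus on.
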