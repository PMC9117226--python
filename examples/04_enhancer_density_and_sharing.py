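"""Intergenic enhancer density, spacing, and cross-tissue site sharing.

Counts accessible sites per gene's intergenic region (a gap peak credits
both flanking genes), filters H3K27ac peaks to active enhancers (> 3 kb
from any TSS), measures nearest-enhancer spacings, and clusters pooled
ATAC midpoints at 1 kb into common / tissue-specific sites.
"""

from intergenic import (
    SyntheticConfig,
    build_neighbor_contexts,
    classify_site_sharing,
    count_intergenic_peaks,
    enhancer_spacing,
    filter_active_enhancers,
    generate_bundle,
)
from intergenic.synthetic import NEURAL_TISSUES, NONNEURAL_TISSUES

bundle = generate_bundle(SyntheticConfig(
    seed=42, n_chromosomes=2, genes_per_chromosome=1000))
contexts = build_neighbor_contexts(bundle.universe)
eid = contexts[contexts["length_class"] == "EID"]

counts = count_intergenic_peaks(bundle.atac, eid, bundle.universe)
neural_mean = counts[list(NEURAL_TISSUES)].mean().mean()
nonneural_mean = counts[list(NONNEURAL_TISSUES)].mean().mean()
print(f"EID genes: {len(eid)}")
print(f"mean intergenic ATAC peaks per EID gene: "
      f"neural {neural_mean:.1f}, non-neural {nonneural_mean:.1f} "
      f"(ratio {neural_mean / nonneural_mean:.2f})")
# ~2x: long intergenic regions hold twice as many accessible sites in
# neural tissues.

for tissue in ("cortex", "heart"):
    peaks = bundle.h3k27ac[bundle.h3k27ac["tissue"] == tissue]
    active = filter_active_enhancers(peaks, bundle.universe)
    spacing = enhancer_spacing(active, contexts, bundle.universe)
    print(f"{tissue:7s}: {len(active)} active enhancers, median spacing "
          f"between nearest enhancers {spacing['spacing_bp'].median()/1000:.1f} kb")
# Neural enhancers are dispersed (~15 kb apart); non-neural ones cluster.

panel = list(NEURAL_TISSUES)
sharing = classify_site_sharing(
    bundle.atac[bundle.atac["tissue"].isin(panel)], panel)
summary = sharing.clusters["sharing_class"].str.replace(
    r"specific:.*", "tissue-specific", regex=True).value_counts()
print("\naccessible-site sharing across the 4 neural tissues:")
print(summary.to_string())
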