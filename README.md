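# intergenic

Analysis pipeline for the relationship between **intergenic DNA length**
and **tissue-specific gene expression**, built around the observation that
mammalian genes flanked by very long intergenic regions are preferentially
expressed in neural tissues and repressed elsewhere.

The package is for computational genomicists who want to reproduce or
extend this style of analysis on their own annotations, expression tables,
peak calls, SNP lists and enhancer–promoter interaction lists — and to
validate every stage against synthetic data with planted ground truth.

## The quantities it computes

For a focal gene *B* with nearest protein-coding neighbors *A* (left) and
*C* (right), the **intergenic length** is

```
L(B) = x + y,   x = start(B) − end(A),   y = start(C) − end(B)
```

Genes with `L > 500 kb` are **EID** genes (extremely long intergenic DNA);
`L > 100 kb` is *extended*, `L < 10 kb` is *short*. Adjacent pairs are
oriented head-to-head (−/+, divergent), tail-to-head (+/+), head-to-tail
(−/−) or tail-to-tail (+/−, convergent), and share the single gap between
them.

**Induction** of gene *g* in tissue *t* is the log2 fold-change of
median-normalized, pseudocounted FPKM against a reference sample *r*
(ES cells, or an unstimulated control):

```
ind(g, t) = log2( (FPKM*(g,t) + 0.1) / (FPKM*(g,r) + 0.1) )
```

where `FPKM*` is FPKM divided by the sample's median over all genes.
On top of this sit: exact-size top-k% sets (round half away from zero, so
5% of 18,383 genes is exactly 919), housekeeping (> 2-fold in every
tissue) and generic-neural (> 2-fold in all neural, none non-neural)
classes, 200-gene binned mean curves with a 3-bin moving average, and
pooled-variance two-sample t-test matrices.

Regulatory layers: peak midpoints assigned to intergenic gaps (a gap peak
credits both flanking genes), active enhancers (H3K27ac midpoint > 3 kb
from any TSS), nearest-enhancer spacings, 1-kb single-linkage clustering
of accessible sites across tissues (common vs tissue-specific), the SNP
chain (discard SNPs within 1 kb of each other, drop genic loci, credit
intergenic loci to both flanking genes), and enhancer–promoter interaction
classification (one neighbor / both neighbors / other only).

## Worked example

Every capability has a narrative script under `examples/`. For instance
enhancer density and sharing (`python examples/04_enhancer_density_and_sharing.py`):

```
EID genes: 90
mean intergenic ATAC peaks per EID gene: neural 15.9, non-neural 8.0 (ratio 2.00)
cortex : 3243 active enhancers, median spacing between nearest enhancers 16.7 kb
heart  : 2793 active enhancers, median spacing between nearest enhancers 11.1 kb

accessible-site sharing across the 4 neural tissues:
tissue-specific    12690
common               768
```

EID genes carry twice as many accessible intergenic sites in neural
tissues as in non-neural ones, neural enhancers are dispersed (~15 kb
apart) rather than densely clustered, and most accessible sites are
specific to one tissue while a small CTCF-like fraction is shared by all
four. Interaction classification
(`python examples/06_interaction_classes.py`):

```
interaction filter funnel:
  input           3643
  protein_coding  3576
  intergenic      3509
  eid             1388
distinct EID-hosted enhancers: 1319, target genes: 314

per-enhancer neighbor-targeting classes:
  one_neighbor     73.2%  (966)
  both_neighbors    5.2%  (69)
  other_only       21.5%  (284)
```

About three quarters of intergenic enhancers of EID genes contact exactly
one of their two flanking genes; only ~5% loop to both.

All inputs here come from the bundled synthetic generator
(`intergenic.generate_bundle`), which plants class-conditional intergenic
spacing, tissue-dependent induction, peak densities, shared sites,
clustered SNPs and interaction classes — with a ground-truth label on
every record, so pipeline output can be scored exactly.

## Layout

| Module | Contents |
| --- | --- |
| `intergenic.annotation` | gene spans, neighbor contexts, pairs, orientations |
| `intergenic.expression` | normalization, induction, top-k and breadth classes |
| `intergenic.curves` | binned mean curves, pairwise t-test matrices |
| `intergenic.regulatory` | peak counting, active enhancers, spacing, sharing |
| `intergenic.variants` | SNP reduction and intergenic host assignment |
| `intergenic.looping` | interaction filter chain and neighbor classification |
| `intergenic.coexpression` | pair induction tables, stimulus co-activation |
| `intergenic.synthetic` | planted-ground-truth data generator |

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
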