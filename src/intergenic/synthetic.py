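"""Synthetic annotation / expression / peak / SNP / interaction bundles.

Every record carries a planted ground-truth label so each pipeline stage
can be validated record-by-record without external downloads.  The
defaults are set to the scale of the mammalian observations the pipeline
is built around: neural-class intergenic spacing medians of 145 kb versus
60 kb for non-neural classes, a 2:1 neural/non-neural intergenic
accessible-site density, enhancer spacings near 15 kb (neural) and 5 kb
(non-neural), 72.2% / 4.5% one-/both-neighbor enhancer-interaction
classes, and the clustered/genic/intergenic SNP proportions of published
disease-risk lists.

Design notes
------------
* Inter-gene gaps, not gene starts, are the primitive random variable:
  genes are laid down left to right with the gap ahead of each gene drawn
  from the class-conditional log-normal spacing distribution, so genes
  never overlap and intergenic-length distributions are controlled
  directly.
* Gene classes follow a Markov chain along each chromosome (persistence
  0.8 by default) so neural genes cluster with neural neighbors and share
  long gaps, as they do in real genomes.
* Accessible sites are one site process per gap with at least 5 kb between
  distinct sites; common (CTCF-like) sites replicate across every tissue
  with small Gaussian jitter, tissue-specific sites appear once.  The
  per-tissue thinning keeps the planted per-tissue density rates exact.
* All randomness flows from one seed through named substreams (one per
  generator stage), so adding a stage never perturbs the others, and the
  same seed yields a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _io
from .annotation import GeneUniverse
from .errors import ValidationError

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticBundle",
           "generate_genome", "generate_expression", "generate_regulatory",
           "generate_stimulus", "generate_bundle", "write_bundle"]

CLASSES = ("housekeeping", "generic_neural", "tissue_specific_neural",
           "nonneural_specific", "background")

NEURAL_TISSUES = ("forebrain", "cortex", "hippocampus", "motor_neuron")
NONNEURAL_TISSUES = ("heart", "intestine", "kidney", "lung")
REFERENCE_SAMPLE = "ES"

_STAGES = {"genome": 1, "expression": 2, "peaks": 3, "snps": 4,
           "interactions": 5, "stimulus": 6}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Named RNG substream for one generator stage."""
    return np.random.default_rng([int(seed) % (2 ** 31), _STAGES[stage]])


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic bundle (defaults = study-scale values)."""

    seed: int = 0
    n_chromosomes: int = 5
    genes_per_chromosome: int = 4000

    # gene classes and their spacing structure
    class_proportions: dict = field(default_factory=lambda: {
        "housekeeping": 0.044, "generic_neural": 0.064,
        "tissue_specific_neural": 0.10, "nonneural_specific": 0.10,
        "background": 0.692})
    class_persistence: float = 0.8
    spacing_median_bp: dict = field(default_factory=lambda: {
        "housekeeping": 30_000, "generic_neural": 145_000,
        "tissue_specific_neural": 145_000, "nonneural_specific": 60_000,
        "background": 60_000})
    spacing_sigma: float = 0.8
    gene_length_median_bp: int = 20_000
    gene_length_sigma: float = 0.7
    min_gap_bp: int = 2_000
    noncoding_gene_fraction: float = 0.02

    # tissue panel
    neural_tissues: tuple = NEURAL_TISSUES
    nonneural_tissues: tuple = NONNEURAL_TISSUES
    reference_sample: str = REFERENCE_SAMPLE

    # expression model
    baseline_median_fpkm: float = 5.0
    baseline_sigma: float = 1.0
    housekeeping_effect: float = 6.0
    induced_effect: float = 8.0
    noise_sigma: float = 0.2

    # accessible sites (rates per 100 kb per tissue)
    atac_rate_neural: float = 2.0
    atac_rate_nonneural: float = 1.0
    atac_common_rate: float = 0.4
    site_min_separation_bp: int = 5_000
    site_jitter_sd_bp: float = 150.0
    peak_halfwidth_bp: int = 250

    # H3K27ac enhancers (rates per 100 kb)
    h3k27ac_active_rate_neural: float = 4.62
    h3k27ac_active_rate_nonneural: float = 13.86
    h3k27ac_background_rate: float = 1.0
    promoter_peak_prob: float = 0.8

    # SNPs
    n_snps: int = 4000
    snp_cluster_fraction: float = 0.621
    snp_genic_fraction: float = 0.508

    # enhancer-promoter interactions
    interaction_probs: tuple = (0.722, 0.045, 0.233)  # one / both / other
    nonpc_interaction_fraction: float = 0.02
    genic_enhancer_fraction: float = 0.02

    # stimulus response
    stimulus_focal_counts: dict = field(default_factory=lambda: {
        "kcl": 202, "bdnf": 118, "forskolin": 170})
    stimulus_focal_induction_prob: float = 0.722
    stimulus_neighbor_induction_prob: float = 0.055
    stimulus_effect: float = 6.0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"class proportions must sum to 1, got {total}")
        if set(self.class_proportions) != set(CLASSES):
            raise ValidationError(
                f"class proportions must cover exactly {CLASSES}")
        for cls, m in self.spacing_median_bp.items():
            if m <= self.min_gap_bp:
                raise ValidationError(
                    f"spacing median for {cls} ({m}) must exceed the gap "
                    f"floor ({self.min_gap_bp})")
        if abs(sum(self.interaction_probs) - 1.0) > 1e-9:
            raise ValidationError("interaction class probabilities must sum to 1")
        for name, v in (("atac_rate_neural", self.atac_rate_neural),
                        ("atac_rate_nonneural", self.atac_rate_nonneural)):
            if v < self.atac_common_rate:
                raise ValidationError(
                    f"{name} must be >= atac_common_rate")

    @property
    def tissues(self) -> tuple:
        return tuple(self.neural_tissues) + tuple(self.nonneural_tissues)

    @property
    def samples(self) -> tuple:
        return (self.reference_sample,) + self.tissues

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted labels covering every generated record."""

    genes: pd.DataFrame = None        # class, target tissue, x, y, length, eid
    gaps: pd.DataFrame = None         # gap intervals with class of left gene
    noncoding: pd.DataFrame = None    # extra non-coding annotation rows
    atac_sites: pd.DataFrame = None   # site_id, sharing, tissue
    snps: pd.DataFrame = None         # id, label
    enhancers: pd.DataFrame = None    # enhancer_id, class, eid flag
    interactions: pd.DataFrame = None # per-record filter-stage label
    stimulus: pd.DataFrame = None     # focal/neighbor planted inductions


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    universe: GeneUniverse
    annotation: pd.DataFrame          # coding + noncoding gene rows
    truth: GroundTruth
    expression: pd.DataFrame          # gene x sample FPKM
    stimulus_expression: pd.DataFrame # gene x (control + stimuli) FPKM
    atac: pd.DataFrame
    h3k27ac: pd.DataFrame
    snps: pd.DataFrame
    interactions: pd.DataFrame


# ------------------------------------------------------------------ genome

def _markov_classes(rng, n: int, proportions: dict,
                    persistence: float) -> np.ndarray:
    """Class labels with run structure; the marginal stays `proportions`."""
    names = np.array(CLASSES)
    p = np.array([proportions[c] for c in CLASSES])
    fresh = rng.choice(len(CLASSES), size=n, p=p)
    keep = rng.random(n) < persistence
    keep[0] = False
    run_id = np.cumsum(~keep) - 1
    run_start_class = fresh[~keep]
    return names[run_start_class[run_id]]


def generate_genome(config: SyntheticConfig
                    ) -> tuple[GeneUniverse, GroundTruth]:
    """Lay down gene spans with class-conditional inter-gene gaps.

    The gap ahead of gene *i* (between genes *i-1* and *i*) is drawn from
    the spacing distribution of the class of gene *i-1* (the leading gap
    of a chromosome uses the first gene's class), so a gene flanked by
    same-class genes has both flanks at its class scale.
    """
    rng = _rng(config.seed, "genome")
    gene_rows, gap_rows, nc_rows = [], [], []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1:02d}"
        n = config.genes_per_chromosome
        classes = _markov_classes(rng, n, config.class_proportions,
                                  config.class_persistence)
        target = np.full(n, "", dtype=object)
        is_ts = classes == "tissue_specific_neural"
        target[is_ts] = rng.choice(list(config.neural_tissues),
                                   size=int(is_ts.sum()))
        is_nn = classes == "nonneural_specific"
        target[is_nn] = rng.choice(list(config.nonneural_tissues),
                                   size=int(is_nn.sum()))

        gap_class = np.r_[classes[:1], classes[:-1]]
        medians = np.array([config.spacing_median_bp[c] for c in gap_class],
                           dtype=float)
        gaps = np.maximum(
            config.min_gap_bp,
            rng.lognormal(np.log(medians), config.spacing_sigma)
        ).astype(np.int64)
        lengths = np.maximum(
            1000,
            rng.lognormal(np.log(config.gene_length_median_bp),
                          config.gene_length_sigma, size=n)
        ).astype(np.int64)
        starts = np.cumsum(gaps) + np.r_[0, np.cumsum(lengths[:-1])]
        ends = starts + lengths
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        ids = np.array([f"g{ci + 1:02d}_{i:05d}" for i in range(n)])

        x = gaps.astype(float)
        y = np.r_[gaps[1:].astype(float), np.nan]
        x[0] = np.nan  # terminal genes have no neighbor context
        intergenic = x + y
        for i in range(n):
            gene_rows.append((ids[i], chrom, int(starts[i]), int(ends[i]),
                              strands[i], "protein_coding", classes[i],
                              target[i], x[i], y[i], intergenic[i]))
        for i in range(n - 1):
            gap_rows.append((chrom, int(ends[i]), int(starts[i + 1]),
                             ids[i], ids[i + 1], classes[i],
                             target[i]))

        n_nc = int(round(config.noncoding_gene_fraction * n))
        if n_nc:
            big = np.nonzero(gaps[1:] >= 20_000)[0]  # interior gaps
            chosen = rng.choice(big, size=min(n_nc, len(big)), replace=False)
            for k, gi in enumerate(sorted(chosen)):
                mid = (ends[gi] + starts[gi + 1]) // 2
                nc_rows.append((f"nc{ci + 1:02d}_{k:04d}", chrom,
                                int(mid - 500), int(mid + 500),
                                "+" if rng.random() < 0.5 else "-", "lncRNA"))

    genes = pd.DataFrame(gene_rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "biotype",
        "class_label", "target_tissue", "upstream_gap_bp",
        "downstream_gap_bp", "intergenic_length_bp"])
    genes["is_eid"] = genes["intergenic_length_bp"] > 500_000
    gaps_df = pd.DataFrame(gap_rows, columns=[
        "chrom", "start", "end", "left_gene_id", "right_gene_id",
        "gap_class", "gap_target_tissue"])
    gaps_df["length"] = gaps_df["end"] - gaps_df["start"]
    noncoding = pd.DataFrame(nc_rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "biotype"])

    universe = GeneUniverse(
        genes[["gene_id", "chrom", "start", "end", "strand", "biotype"]],
        provenance=f"synthetic(seed={config.seed})")
    truth = GroundTruth(genes=genes, gaps=gaps_df, noncoding=noncoding)
    return universe, truth


# -------------------------------------------------------------- expression

def _class_effect(config: SyntheticConfig, classes: np.ndarray,
                  targets: np.ndarray) -> pd.DataFrame:
    """Planted multiplicative effect per gene x tissue (reference = 1)."""
    n = len(classes)
    eff = pd.DataFrame(1.0, index=np.arange(n), columns=list(config.tissues))
    hk = classes == "housekeeping"
    eff.loc[hk, :] = config.housekeeping_effect
    gn = classes == "generic_neural"
    eff.loc[gn, list(config.neural_tissues)] = config.induced_effect
    for t in config.tissues:
        spec = (targets == t)
        eff.loc[spec, t] = config.induced_effect
    return eff


def generate_expression(universe: GeneUniverse, truth: GroundTruth,
                        config: SyntheticConfig) -> pd.DataFrame:
    """FPKM matrix: log-normal baseline x planted class effect x noise."""
    rng = _rng(config.seed, "expression")
    genes = truth.genes
    n = len(genes)
    baseline = rng.lognormal(np.log(config.baseline_median_fpkm),
                             config.baseline_sigma, size=n)
    eff = _class_effect(config, genes["class_label"].to_numpy(),
                        genes["target_tissue"].to_numpy())
    samples = list(config.samples)
    noise = rng.lognormal(0.0, config.noise_sigma, size=(n, len(samples))) \
        if config.noise_sigma > 0 else np.ones((n, len(samples)))
    values = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        e = np.ones(n) if s == config.reference_sample \
            else eff[s].to_numpy()
        values[:, j] = baseline * e * noise[:, j]
    return pd.DataFrame(values, index=pd.Index(genes["gene_id"],
                                               name="gene_id"),
                        columns=samples)


def planted_effect_table(truth: GroundTruth,
                         config: SyntheticConfig) -> pd.DataFrame:
    """The noiseless planted induction effects, indexed by gene_id.

    Ranking genes by these effects gives the ground-truth ordering that the
    expression-based ranking is expected to recover; recovery metrics
    compare selections made from measured induction against selections made
    from this table.
    """
    genes = truth.genes
    eff = _class_effect(config, genes["class_label"].to_numpy(),
                        genes["target_tissue"].to_numpy())
    eff.index = pd.Index(genes["gene_id"], name="gene_id")
    return eff


# -------------------------------------------------------------- regulatory

def _hardcore_positions(rng, gap_start, gap_len, owner_counts,
                        sep: int, margin: int):
    """Positions per gap with pairwise separation >= `sep`.

    ``owner_counts`` is a (n_gaps, n_categories) count matrix; returns
    (gap_index, category, position) arrays with counts capped by gap
    capacity (events dropped uniformly at random when a gap is full).
    """
    n_gaps, n_cat = owner_counts.shape
    cap = np.maximum(0, (gap_len - 2 * margin) // sep + 1)
    cap[gap_len < 2 * margin] = 0
    counts = owner_counts.ravel()
    gap_ids = np.repeat(np.repeat(np.arange(n_gaps), n_cat), counts)
    cat_ids = np.repeat(np.tile(np.arange(n_cat), n_gaps), counts)
    if len(gap_ids) == 0:
        return (np.array([], dtype=int),) * 2 + (np.array([], dtype=np.int64),)
    # random order within each gap, then cap
    perm = rng.permutation(len(gap_ids))
    g, c = gap_ids[perm], cat_ids[perm]
    o = np.argsort(g, kind="stable")
    g, c = g[o], c[o]
    m_all = np.bincount(g, minlength=n_gaps)
    first = np.r_[0, np.cumsum(m_all)[:-1]]
    rank = np.arange(len(g)) - first[g]
    keep = rank < cap[g]
    g, c = g[keep], c[keep]
    # spread uniforms, sort within gap, add k*sep
    m = np.bincount(g, minlength=n_gaps)
    span = np.maximum(1, gap_len - 2 * margin - (m - 1) * sep)
    u = rng.random(len(g)) * span[g]
    o2 = np.lexsort((u, g))
    g, c, u = g[o2], c[o2], u[o2]
    first2 = np.r_[0, np.cumsum(m)[:-1]]
    rank2 = np.arange(len(g)) - first2[g]
    pos = (gap_start[g] + margin + u).astype(np.int64) + rank2 * sep
    return g, c, pos


def _generate_atac(rng, truth: GroundTruth, config: SyntheticConfig):
    gaps = truth.gaps
    L = gaps["length"].to_numpy()
    tissues = list(config.tissues)
    neural = set(config.neural_tissues)
    lam = [config.atac_common_rate] + [
        (config.atac_rate_neural if t in neural
         else config.atac_rate_nonneural) - config.atac_common_rate
        for t in tissues]
    lam = np.array(lam) / 100_000.0
    counts = rng.poisson(np.outer(L, lam))
    g, c, pos = _hardcore_positions(
        rng, gaps["start"].to_numpy(), L, counts,
        sep=config.site_min_separation_bp, margin=500)
    site_id = np.arange(len(g))
    is_common = c == 0
    site_tissue = np.where(is_common, "",
                           np.array([""] + tissues, dtype=object)[c])
    sites = pd.DataFrame({
        "site_id": site_id,
        "chrom": gaps["chrom"].to_numpy()[g],
        "gap_index": g,
        "center": pos,
        "sharing": np.where(is_common, "common", "specific"),
        "tissue": site_tissue,
    })
    # expand to per-tissue peaks
    hw = config.peak_halfwidth_bp
    frames = []
    common = sites[sites["sharing"] == "common"]
    if len(common):
        for t in tissues:
            jitter = np.rint(rng.normal(
                0, config.site_jitter_sd_bp, size=len(common))).astype(np.int64)
            center = common["center"].to_numpy() + jitter
            frames.append(pd.DataFrame({
                "chrom": common["chrom"].to_numpy(),
                "start": center - hw, "end": center + hw,
                "tissue": t, "assay": "ATAC",
                "site_id": common["site_id"].to_numpy(),
            }))
    spec = sites[sites["sharing"] == "specific"]
    frames.append(pd.DataFrame({
        "chrom": spec["chrom"].to_numpy(),
        "start": spec["center"].to_numpy() - hw,
        "end": spec["center"].to_numpy() + hw,
        "tissue": spec["tissue"].to_numpy(),
        "assay": "ATAC",
        "site_id": spec["site_id"].to_numpy(),
    }))
    atac = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "tissue"], kind="mergesort").reset_index(drop=True)
    return atac, sites


def _gap_active_in(gaps: pd.DataFrame, tissue: str,
                   config: SyntheticConfig) -> np.ndarray:
    """Planted enhancer activity of each gap in one tissue."""
    cls = gaps["gap_class"].to_numpy()
    tgt = gaps["gap_target_tissue"].to_numpy()
    neural = tissue in set(config.neural_tissues)
    return ((cls == "housekeeping")
            | ((cls == "generic_neural") & neural)
            | (tgt == tissue))


def _generate_h3k27ac(rng, universe: GeneUniverse, truth: GroundTruth,
                      config: SyntheticConfig) -> pd.DataFrame:
    gaps = truth.gaps
    L = gaps["length"].to_numpy().astype(float)
    neural = set(config.neural_tissues)
    frames = []
    hw = config.peak_halfwidth_bp
    for t in config.tissues:
        active = _gap_active_in(gaps, t, config)
        active_rate = (config.h3k27ac_active_rate_neural if t in neural
                       else config.h3k27ac_active_rate_nonneural)
        rate = np.where(active, active_rate,
                        config.h3k27ac_background_rate) / 100_000.0
        counts = rng.poisson(rate * L)
        gi = np.repeat(np.arange(len(gaps)), counts)
        u = rng.random(len(gi))
        pos = (gaps["start"].to_numpy()[gi] + 100
               + u * (L[gi] - 200)).astype(np.int64)
        frames.append(pd.DataFrame({
            "chrom": gaps["chrom"].to_numpy()[gi],
            "start": pos - hw, "end": pos + hw,
            "tissue": t, "assay": "H3K27ac",
            "gap_index": gi,
        }))
        # promoter-proximal peaks of genes active in this tissue
        genes = truth.genes
        eff_active = ((genes["class_label"] == "housekeeping")
                      | ((genes["class_label"] == "generic_neural")
                         & (t in neural))
                      | (genes["target_tissue"] == t)).to_numpy()
        chosen = eff_active & (rng.random(len(genes))
                               < config.promoter_peak_prob)
        tss = universe.tss()[genes.loc[chosen, "gene_id"]].to_numpy()
        offs = rng.integers(-1000, 1001, size=chosen.sum())
        frames.append(pd.DataFrame({
            "chrom": genes.loc[chosen, "chrom"].to_numpy(),
            "start": tss + offs - hw, "end": tss + offs + hw,
            "tissue": t, "assay": "H3K27ac",
            "gap_index": -1,
        }))
    return pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "tissue"], kind="mergesort").reset_index(drop=True)


def _generate_snps(rng, truth: GroundTruth, config: SyntheticConfig):
    """Grid-based SNP placement with planted clustered/genic/intergenic labels.

    Candidate positions sit on 2.5-kb grids inside gene bodies and gap
    interiors (1.2 kb margins), jittered by up to 200 bp, so any two
    distinct units are more than 1 kb apart; clustered SNPs add satellites
    within 900 bp of their base and are the only casualties of the 1-kb
    exclusion.
    """
    genes = truth.genes
    gaps = truth.gaps
    margin, step, jit = 1200, 2500, 200

    def grid(starts, ends, chroms):
        rows = []
        for s, e, c in zip(starts, ends, chroms):
            lo, hi = s + margin, e - margin
            if hi <= lo:
                continue
            k = (hi - lo) // step + 1
            rows.append((c, lo, k))
        chrom_r = np.concatenate([np.repeat(c, k) for c, _, k in rows]) \
            if rows else np.array([], dtype=object)
        base = np.concatenate([lo + step * np.arange(k) for _, lo, k in rows]) \
            if rows else np.array([], dtype=np.int64)
        return chrom_r, base

    genic_chrom, genic_base = grid(genes["start"].to_numpy(),
                                   genes["end"].to_numpy(),
                                   genes["chrom"].to_numpy())
    inter_chrom, inter_base = grid(gaps["start"].to_numpy(),
                                   gaps["end"].to_numpy(),
                                   gaps["chrom"].to_numpy())

    n_total = config.n_snps
    target_clustered = int(round(n_total * config.snp_cluster_fraction))
    sizes = []
    while sum(sizes) < target_clustered:
        sizes.append(int(rng.integers(2, 4)))
    n_clustered = sum(sizes)
    n_single = max(0, n_total - n_clustered)
    n_genic = int(round(n_single * config.snp_genic_fraction))
    n_inter = n_single - n_genic

    pick_g = rng.choice(len(genic_base), size=n_genic + len(sizes) // 2,
                        replace=False)
    pick_i = rng.choice(len(inter_base), size=n_inter + (len(sizes)
                                                         - len(sizes) // 2),
                        replace=False)
    rows = []
    for j in range(n_genic):
        p = int(genic_base[pick_g[j]] + rng.integers(-jit, jit + 1))
        rows.append((genic_chrom[pick_g[j]], p, "genic"))
    for j in range(n_inter):
        p = int(inter_base[pick_i[j]] + rng.integers(-jit, jit + 1))
        rows.append((inter_chrom[pick_i[j]], p, "intergenic"))
    bases = ([(genic_chrom[pick_g[n_genic + j]],
               genic_base[pick_g[n_genic + j]])
              for j in range(len(sizes) // 2)]
             + [(inter_chrom[pick_i[n_inter + j]],
                 inter_base[pick_i[n_inter + j]])
                for j in range(len(sizes) - len(sizes) // 2)])
    for (chrom, base), size in zip(bases, sizes):
        offs = [0] + list(rng.integers(150, 901, size=size - 1))
        for o in offs:
            rows.append((chrom, int(base + o), "clustered"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "label"])
    df = df.sort_values(["chrom", "pos"], kind="mergesort"
                        ).reset_index(drop=True)
    df["id"] = [f"snp{i:05d}" for i in range(len(df))]
    snps = df[["chrom", "pos", "id"]].copy()
    truth_snps = df[["id", "chrom", "pos", "label"]].copy()
    return snps, truth_snps


def _generate_interactions(rng, universe: GeneUniverse, truth: GroundTruth,
                           h3k27ac: pd.DataFrame, config: SyntheticConfig):
    """Interaction records per intergenic cortex enhancer + planted labels."""
    gaps = truth.gaps
    genes = truth.genes.set_index("gene_id")
    tss = universe.tss()
    gdf = universe.df.reset_index(drop=True)
    gene_pos = {g: i for i, g in enumerate(gdf["gene_id"])}

    enh = h3k27ac[(h3k27ac["tissue"] == "cortex")
                  & (h3k27ac["gap_index"] >= 0)]
    enh = enh.drop_duplicates(["chrom", "start", "end"]).reset_index(drop=True)
    gi = enh["gap_index"].to_numpy()
    left = gaps["left_gene_id"].to_numpy()[gi]
    right = gaps["right_gene_id"].to_numpy()[gi]
    eid_left = genes["is_eid"].reindex(left).fillna(False).to_numpy()
    eid_right = genes["is_eid"].reindex(right).fillna(False).to_numpy()
    is_eid = eid_left | eid_right

    cls = rng.choice(["one_neighbor", "both_neighbors", "other_only"],
                     size=len(enh), p=list(config.interaction_probs))
    stage_of = np.where(is_eid, "eid", "non_eid_intergenic")
    gene_ids_arr = gdf["gene_id"].to_numpy()
    idx_by_chrom = pd.Series(np.arange(len(gdf)), index=gdf["chrom"])
    chrom_lo = idx_by_chrom.groupby(level=0).min()
    chrom_hi = idx_by_chrom.groupby(level=0).max()

    echrom = enh["chrom"].to_numpy()
    estart = enh["start"].to_numpy()
    eend = enh["end"].to_numpy()

    def _records(mask, targets):
        return pd.DataFrame({
            "chrom": echrom[mask], "start": estart[mask],
            "end": eend[mask], "gene_id": targets,
            "tss": tss[targets].to_numpy(),
        }), list(stage_of[mask])

    one = cls == "one_neighbor"
    pick_right = rng.random(int(one.sum())) < 0.5
    one_targets = np.where(pick_right, right[one], left[one])
    both = cls == "both_neighbors"
    other = cls == "other_only"
    off = rng.integers(3, 10, size=int(other.sum()))
    neg = rng.random(int(other.sum())) < 0.5
    off = np.where(neg, -off + 1, off)   # {-8..-2} or {3..9}
    i_pos = np.array([gene_pos[g] for g in left[other]], dtype=np.int64)
    lo = chrom_lo[echrom[other]].to_numpy()
    hi = chrom_hi[echrom[other]].to_numpy()
    j = np.clip(i_pos + off, lo, hi)
    collide = (j == i_pos) | (j == i_pos + 1)
    j[collide] = np.where(i_pos[collide] - 2 >= lo[collide],
                          i_pos[collide] - 2, i_pos[collide] + 3)
    j = np.clip(j, lo, hi)
    other_targets = gene_ids_arr[j]

    frames, stage = [], []
    for mask, targets in ((one, one_targets),
                          (both, left[both]), (both, right[both]),
                          (other, other_targets)):
        f, s = _records(mask, targets)
        frames.append(f)
        stage.extend(s)
    main = pd.concat(frames, ignore_index=True)
    rec = list(main.itertuples(index=False, name=None))

    # planted drop-outs for the first two filter stages
    n_main = len(enh)
    n_nonpc = int(round(config.nonpc_interaction_fraction * n_main))
    nc = truth.noncoding
    if n_nonpc and len(nc):
        gsel = rng.choice(len(gaps), size=n_nonpc)
        ncsel = rng.choice(len(nc), size=n_nonpc)
        for g_i, nc_i in zip(gsel, ncsel):
            gp = gaps.iloc[g_i]
            pos = int(gp["start"] + 700 + rng.integers(0, max(1, gp["length"]
                                                              - 1400)))
            row = nc.iloc[nc_i]
            rec.append((gp["chrom"], pos - 250, pos + 250, row["gene_id"],
                        int(row["start"])))
            stage.append("non_protein_coding")
    n_genic = int(round(config.genic_enhancer_fraction * n_main))
    if n_genic:
        sel = rng.choice(len(gdf), size=n_genic)
        tsel = rng.choice(len(gdf), size=n_genic)
        for s_i, t_i in zip(sel, tsel):
            row = gdf.iloc[s_i]
            mid = int((row["start"] + row["end"]) // 2)
            tgene = gdf["gene_id"].iloc[t_i]
            rec.append((row["chrom"], mid - 250, mid + 250, tgene,
                        int(tss[tgene])))
            stage.append("genic_enhancer")

    interactions = pd.DataFrame(rec, columns=["chrom", "start", "end",
                                              "gene_id", "tss"])
    truth_inter = interactions.copy()
    truth_inter["stage"] = stage
    truth_enh = pd.DataFrame({
        "enhancer_id": [f"{c}:{s}-{e}" for c, s, e in
                        zip(enh["chrom"], enh["start"], enh["end"])],
        "chrom": enh["chrom"], "start": enh["start"], "end": enh["end"],
        "gap_index": gi, "interaction_class": cls, "hosts_eid_gene": is_eid,
    })
    return interactions, truth_inter, truth_enh


def generate_regulatory(universe: GeneUniverse, truth: GroundTruth,
                        config: SyntheticConfig):
    """Peaks, SNPs and interactions with ground-truth labels recorded.

    Returns ``(atac, h3k27ac, snps, interactions)`` and fills the
    corresponding ground-truth frames in ``truth``.
    """
    rng = _rng(config.seed, "peaks")
    atac, sites = _generate_atac(rng, truth, config)
    h3k27ac = _generate_h3k27ac(rng, universe, truth, config)
    snp_rng = _rng(config.seed, "snps")
    snps, truth_snps = _generate_snps(snp_rng, truth, config)
    int_rng = _rng(config.seed, "interactions")
    interactions, truth_inter, truth_enh = _generate_interactions(
        int_rng, universe, truth, h3k27ac, config)
    truth.atac_sites = sites
    truth.snps = truth_snps
    truth.interactions = truth_inter
    truth.enhancers = truth_enh
    return atac, h3k27ac, snps, interactions


# ---------------------------------------------------------------- stimulus

def generate_stimulus(universe: GeneUniverse, truth: GroundTruth,
                      config: SyntheticConfig) -> pd.DataFrame:
    """Control + per-stimulus FPKM columns with planted focal/neighbor hits."""
    rng = _rng(config.seed, "stimulus")
    genes = truth.genes
    n = len(genes)
    interior = genes["intergenic_length_bp"].notna().to_numpy()
    idx_interior = np.nonzero(interior)[0]
    baseline = rng.lognormal(np.log(config.baseline_median_fpkm),
                             config.baseline_sigma, size=n)
    cols = {"control": baseline * rng.lognormal(0, config.noise_sigma, n)}
    ids = genes["gene_id"].to_numpy()
    pos = {g: i for i, g in enumerate(ids)}
    truth_rows = []
    for stim, n_focal in config.stimulus_focal_counts.items():
        # focal genes are kept non-adjacent so each neighbor slot reflects
        # the planted neighbor co-activation probability, not focal overlap
        chosen: list[int] = []
        taken: set[int] = set()
        for i in rng.permutation(idx_interior):
            i = int(i)
            if {i - 1, i, i + 1} & taken:
                continue
            chosen.append(i)
            taken.add(i)
            if len(chosen) == n_focal:
                break
        focal_idx = np.array(sorted(chosen), dtype=np.int64)
        focal_set = set(focal_idx.tolist())
        eff = np.ones(n)
        focal_hit = rng.random(len(focal_idx)) \
            < config.stimulus_focal_induction_prob
        eff[focal_idx[focal_hit]] = config.stimulus_effect
        for fi, hit in zip(focal_idx, focal_hit):
            truth_rows.append((stim, ids[fi], "focal", bool(hit)))
            for nb in (fi - 1, fi + 1):
                if 0 <= nb < n and nb not in focal_set \
                        and genes["chrom"].iloc[nb] == genes["chrom"].iloc[fi]:
                    nb_hit = rng.random() < \
                        config.stimulus_neighbor_induction_prob
                    if nb_hit:
                        eff[nb] = config.stimulus_effect
                    truth_rows.append((stim, ids[nb], "neighbor",
                                       bool(nb_hit)))
        cols[stim] = baseline * eff * rng.lognormal(0, config.noise_sigma, n)
    truth.stimulus = pd.DataFrame(
        truth_rows, columns=["stimulus", "gene_id", "role", "induced"])
    return pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))


# ------------------------------------------------------------------ bundle

def generate_bundle(config: SyntheticConfig | None = None,
                    seed: int | None = None) -> SyntheticBundle:
    """Generate the full synthetic bundle under one seed."""
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    universe, truth = generate_genome(config)
    expression = generate_expression(universe, truth, config)
    atac, h3k27ac, snps, interactions = generate_regulatory(
        universe, truth, config)
    stimulus = generate_stimulus(universe, truth, config)
    annotation = pd.concat([
        universe.df,
        truth.noncoding[["gene_id", "chrom", "start", "end", "strand",
                         "biotype"]],
    ], ignore_index=True).sort_values(
        ["chrom", "start", "gene_id"], kind="mergesort").reset_index(drop=True)
    return SyntheticBundle(
        config=config, universe=universe, annotation=annotation,
        truth=truth, expression=expression, stimulus_expression=stimulus,
        atac=atac, h3k27ac=h3k27ac, snps=snps, interactions=interactions)


def write_bundle(bundle: SyntheticBundle, outdir):
    """Write the bundle as plain-text files (GTF/TSV/BED + truth tables)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_gtf(bundle.annotation, out / "annotation.gtf")
    _io.write_expression_tsv(bundle.expression, out / "expression.tsv")
    _io.write_expression_tsv(bundle.stimulus_expression,
                             out / "stimulus_expression.tsv")
    _io.write_tsv(bundle.atac.drop(columns=["site_id"]),
                  out / "peaks_atac.tsv")
    _io.write_tsv(bundle.h3k27ac.drop(columns=["gap_index"]),
                  out / "peaks_h3k27ac.tsv")
    _io.write_bed(bundle.snps.assign(start=bundle.snps["pos"],
                                     end=bundle.snps["pos"] + 1),
                  out / "snps.bed", name_col="id")
    _io.write_tsv(bundle.interactions, out / "interactions.tsv")
    tdir = out / "ground_truth"
    tdir.mkdir(exist_ok=True)
    for name in ("genes", "gaps", "noncoding", "atac_sites", "snps",
                 "enhancers", "interactions", "stimulus"):
        df = getattr(bundle.truth, name)
        if df is not None:
            _io.write_tsv(df, tdir / f"{name}.tsv")
    with open(out / "config.json", "w") as fh:
        json.dump(bundle.config.to_dict(), fh, indent=2, sort_keys=True)
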