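"""Enhancer-promoter interaction classification for genes with long
intergenic DNA.

Pre-called enhancer-to-TSS interaction lists (e.g. from Hi-C) are pushed
through a staged filter chain -- (1) the target gene must be a
protein-coding gene of the universe, (2) the enhancer midpoint must lie in
a shared intergenic gap, (3) the hosting gap must belong to a gene with
extremely long intergenic DNA (EID, > 500 kb) -- and each distinct
enhancer is then classified by how its interaction partners intersect the
two genes flanking its gap: exactly one flank (one_neighbor), both flanks
(both_neighbors), or neither (other_only).  Additional distal partners do
not change the class.  Enhancer identity is the exact interval; duplicate
records collapse (set semantics on partners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gaps import assign_points_to_gaps, gap_table
from .annotation import GeneUniverse

__all__ = ["InteractionFilterResult", "EnhancerClassification",
           "filter_interactions", "classify_enhancer_targets"]


@dataclass
class InteractionFilterResult:
    """Staged interaction subsets with per-stage counts."""

    interactions: pd.DataFrame      # stage-3 survivors, with hosting gap
    stage_counts: dict              # input / protein_coding / intergenic / eid
    n_distinct_enhancers: int
    n_distinct_genes: int
    intergenic_stage: pd.DataFrame = field(repr=False, default=None)
    """Stage-2 survivors (intergenic enhancers of any gene), for analyses
    not restricted to EID genes."""


@dataclass
class EnhancerClassification:
    """Per-enhancer neighbor-targeting classes and their fractions."""

    summary: pd.DataFrame   # enhancer_id, chrom, start, end, left/right gene,
                            # n_partners, target_class
    fractions: dict         # class -> fraction of distinct enhancers
    counts: dict            # class -> number of distinct enhancers


def filter_interactions(interactions: pd.DataFrame, universe: GeneUniverse,
                        contexts: pd.DataFrame) -> InteractionFilterResult:
    """Apply the staged filter chain to an interaction list.

    ``interactions`` needs columns ``chrom, start, end, gene_id`` (and
    optionally ``tss``).  Stage counts are returned for every stage so the
    funnel can be compared against published tallies.
    """
    df = interactions.reset_index(drop=True)
    counts = {"input": len(df)}

    pc = set(universe.df["gene_id"])
    df = df[df["gene_id"].isin(pc)].reset_index(drop=True)
    counts["protein_coding"] = len(df)

    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    gaps = gap_table(universe)
    gap_idx = assign_points_to_gaps(df["chrom"].to_numpy(), mid, gaps)
    df = df.assign(enhancer_midpoint=mid, gap_index=gap_idx)
    df = df[df["gap_index"] >= 0].reset_index(drop=True)
    counts["intergenic"] = len(df)

    gi = df["gap_index"].to_numpy()
    df = df.assign(
        left_flank=gaps["left_gene_id"].to_numpy()[gi],
        right_flank=gaps["right_gene_id"].to_numpy()[gi],
    )
    intergenic_stage = df.copy()

    eid_genes = set(
        contexts.loc[contexts["length_class"] == "EID", "gene_id"])
    hosted_by_eid = (df["left_flank"].isin(eid_genes)
                     | df["right_flank"].isin(eid_genes))
    df = df[hosted_by_eid].reset_index(drop=True)
    counts["eid"] = len(df)

    enh = df[["chrom", "start", "end"]].drop_duplicates()
    return InteractionFilterResult(
        interactions=df,
        stage_counts=counts,
        n_distinct_enhancers=len(enh),
        n_distinct_genes=df["gene_id"].nunique(),
        intergenic_stage=intergenic_stage,
    )


def classify_enhancer_targets(filtered: InteractionFilterResult | pd.DataFrame
                              ) -> EnhancerClassification:
    """Classify each distinct enhancer by its flanking-gene partners.

    The partner set of an enhancer (all target genes over its interaction
    records) is intersected with the two genes flanking its hosting gap:
    intersection size 1 -> ``one_neighbor``, 2 -> ``both_neighbors``,
    0 -> ``other_only``.  Fractions are over distinct enhancers and sum
    to 1.
    """
    df = (filtered.interactions
          if isinstance(filtered, InteractionFilterResult) else filtered)
    dedup = df.drop_duplicates(["chrom", "start", "end", "gene_id"])
    dedup = dedup.assign(
        hits_left=dedup["gene_id"] == dedup["left_flank"],
        hits_right=dedup["gene_id"] == dedup["right_flank"],
    )
    summary = (dedup.groupby(["chrom", "start", "end"], sort=True)
               .agg(left_flank=("left_flank", "first"),
                    right_flank=("right_flank", "first"),
                    n_partners=("gene_id", "nunique"),
                    hits_left=("hits_left", "any"),
                    hits_right=("hits_right", "any"))
               .reset_index())
    n_nb = summary["hits_left"].astype(int) + summary["hits_right"].astype(int)
    summary["target_class"] = np.select(
        [n_nb == 1, n_nb == 2], ["one_neighbor", "both_neighbors"],
        default="other_only")
    summary.insert(0, "enhancer_id", [
        f"{c}:{s}-{e}" for c, s, e in
        zip(summary["chrom"], summary["start"], summary["end"])])
    summary = summary.drop(columns=["hits_left", "hits_right"])
    n = len(summary)
    counts = {c: int((summary["target_class"] == c).sum())
              for c in ("one_neighbor", "both_neighbors", "other_only")}
    fractions = {c: (counts[c] / n if n else 0.0) for c in counts}
    return EnhancerClassification(summary=summary, fractions=fractions,
                                  counts=counts)
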