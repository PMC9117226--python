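"""Shared helpers for assigning point coordinates to intergenic gaps and genes.

A "gap" is the shared intergenic interval between two adjacent,
non-overlapping genes; gaps on a chromosome are disjoint by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GeneUniverse, enumerate_gene_pairs


def gap_table(universe: GeneUniverse) -> pd.DataFrame:
    """All shared intergenic intervals with their flanking gene ids.

    Columns: ``chrom, start, end, left_gene_id, right_gene_id``.
    """
    pairs = enumerate_gene_pairs(universe)
    return pairs.rename(
        columns={"shared_start": "start", "shared_end": "end"}
    )[["chrom", "start", "end", "left_gene_id", "right_gene_id"]]


def assign_points_to_gaps(chroms: np.ndarray, positions: np.ndarray,
                          gaps: pd.DataFrame) -> np.ndarray:
    """Index of the gap containing each point, or -1 if none.

    ``gaps`` must come from :func:`gap_table` (disjoint, sorted per
    chromosome); indices refer to rows of that frame.
    """
    out = np.full(len(positions), -1, dtype=np.int64)
    gap_by_chrom = {c: sub for c, sub in gaps.groupby("chrom", sort=False)}
    pos = np.asarray(positions)
    chroms = np.asarray(chroms)
    for c in pd.unique(chroms):
        sub = gap_by_chrom.get(c)
        if sub is None:
            continue
        mask = chroms == c
        p = pos[mask]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cand = np.searchsorted(starts, p, side="right") - 1
        ok = cand >= 0
        ok[ok] &= p[ok] < ends[cand[ok]]
        idx = np.where(ok, sub.index.to_numpy()[np.clip(cand, 0, None)], -1)
        out[mask] = idx
    return out


def points_in_genes(chroms: np.ndarray, positions: np.ndarray,
                    universe: GeneUniverse) -> np.ndarray:
    """True where a point lies inside any gene span (overlaps included)."""
    out = np.zeros(len(positions), dtype=bool)
    pos = np.asarray(positions)
    chroms = np.asarray(chroms)
    genes = {c: sub for c, sub in universe.by_chrom()}
    for c in pd.unique(chroms):
        sub = genes.get(c)
        if sub is None:
            continue
        mask = chroms == c
        p = pos[mask]
        starts = sub["start"].to_numpy()
        prefix_max_end = np.maximum.accumulate(sub["end"].to_numpy())
        cand = np.searchsorted(starts, p, side="right") - 1
        inside = cand >= 0
        inside[inside] &= p[inside] < prefix_max_end[cand[inside]]
        out[mask] = inside
    return out
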