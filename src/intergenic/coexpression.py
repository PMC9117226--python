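"""Neighbor-pair co-expression and stimulus co-activation.

Adjacent gene pairs are grouped by orientation (H-H, T-H, H-T, T-T) and
ordered by the length of their shared intergenic interval; the induction
levels of the left and right genes can then be compared across tissues and
binned against shared length.  For stimulus experiments, the focal
(activity-dependent) genes are compared with their two flanking neighbors:
the co-activation fractions count how many focal genes, and how many of
the pooled upstream/downstream neighbors, clear the >2-fold induction rule
under the stimulus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .curves import BinnedCurve, binned_mean_curve
from .errors import ValidationError
from .expression import InductionTable

__all__ = ["PairInductionTable", "CoactivationResult", "pair_induction_table",
           "coactivation_fractions"]

ORIENTATIONS = ("HH", "TH", "HT", "TT")


@dataclass
class PairInductionTable:
    """Left/right induction of adjacent gene pairs, by orientation group.

    ``table`` rows are sorted by descending shared intergenic length within
    each orientation group and carry ``left_<tissue>`` / ``right_<tissue>``
    induction columns.
    """

    table: pd.DataFrame
    tissues: tuple
    n_dropped: int   # pairs lacking expression for either gene

    def group(self, orientation: str) -> pd.DataFrame:
        if orientation not in ORIENTATIONS:
            raise ValidationError(f"unknown orientation {orientation!r}")
        return self.table[self.table["orientation"] == orientation]

    def binned_curves(self, tissue: str, orientation: str | None = None,
                      bin_size: int = 200) -> dict[str, BinnedCurve]:
        """Binned mean induction of left and right genes vs shared length."""
        sub = self.table if orientation is None else self.group(orientation)
        return {
            side: binned_mean_curve(
                sub[f"{side}_{tissue}"],
                sub["shared_length_bp"],
                bin_size=bin_size,
                sort_key="shared_length_bp",
            )
            for side in ("left", "right")
        }


def pair_induction_table(pairs: pd.DataFrame,
                         induction: InductionTable | pd.DataFrame,
                         tissues=None) -> PairInductionTable:
    """Join adjacent gene pairs with per-tissue induction of both members.

    Pairs whose left or right gene lacks expression are dropped and
    counted.  Within each orientation group, rows are ordered by
    descending shared intergenic length (rank column included).
    """
    log2fc = induction.log2fc if isinstance(induction, InductionTable) \
        else induction
    tissues = list(tissues) if tissues is not None else list(log2fc.columns)
    covered = pairs["left_gene_id"].isin(log2fc.index) \
        & pairs["right_gene_id"].isin(log2fc.index)
    n_dropped = int((~covered).sum())
    table = pairs[covered].copy()
    for t in tissues:
        table[f"left_{t}"] = log2fc.loc[
            table["left_gene_id"], t].to_numpy()
        table[f"right_{t}"] = log2fc.loc[
            table["right_gene_id"], t].to_numpy()
    table = table.sort_values(
        ["orientation", "shared_length_bp", "left_gene_id"],
        ascending=[True, False, True], kind="mergesort",
    ).reset_index(drop=True)
    table["shared_length_rank"] = table.groupby("orientation").cumcount()
    return PairInductionTable(table=table, tissues=tuple(tissues),
                              n_dropped=n_dropped)


@dataclass
class CoactivationResult:
    """Stimulus co-activation of focal genes versus their neighbors."""

    focal_fraction: float
    neighbor_fraction: float
    n_focal: int
    n_focal_induced: int
    n_neighbors: int
    n_neighbors_induced: int
    n_missing_neighbors: int
    per_focal: pd.DataFrame  # gene_id, induced, left/right neighbor + induced


def coactivation_fractions(induction: InductionTable | pd.DataFrame,
                           treated_sample: str,
                           focal_genes,
                           contexts: pd.DataFrame,
                           fold_threshold: float = 2.0) -> CoactivationResult:
    """Fractions of focal genes and of their neighbors induced by a stimulus.

    ``induction`` must be referenced to the unstimulated control (same
    pseudocount/normalization rules as tissue induction).  Neighbors are
    each focal gene's two flanking genes from annotation geometry; focal
    genes without a neighbor context contribute the neighbors they have,
    and the shortfall is reported (and warned about).
    """
    log2fc = induction.log2fc if isinstance(induction, InductionTable) \
        else induction
    if treated_sample not in log2fc.columns:
        raise ValidationError(
            f"treated sample {treated_sample!r} not in induction table")
    thr = math.log2(fold_threshold)
    fc = log2fc[treated_sample]
    focal = [g for g in focal_genes]
    missing_expr = [g for g in focal if g not in fc.index]
    if missing_expr:
        raise ValidationError(
            f"focal gene(s) lack expression: {missing_expr[:5]}")

    ctx = contexts.set_index("gene_id")
    rows = []
    neighbors = []
    n_missing = 0
    for g in focal:
        if g in ctx.index:
            left = ctx.loc[g, "left_neighbor_id"]
            right = ctx.loc[g, "right_neighbor_id"]
        else:
            left = right = None
            n_missing += 2
        for nb in (left, right):
            if nb is not None and nb in fc.index:
                neighbors.append(nb)
            elif nb is not None:
                n_missing += 1
        rows.append((g, bool(fc[g] > thr), left, right))
    if n_missing:
        warnings.warn(
            f"{n_missing} neighbor slot(s) unavailable (terminal, "
            "overlapping, or unexpressed neighbors)", stacklevel=2)
    per_focal = pd.DataFrame(
        rows, columns=["gene_id", "induced", "left_neighbor",
                       "right_neighbor"])
    n_focal_induced = int(per_focal["induced"].sum())
    nb_induced = int((fc[neighbors] > thr).sum()) if neighbors else 0
    return CoactivationResult(
        focal_fraction=n_focal_induced / len(focal) if focal else 0.0,
        neighbor_fraction=nb_induced / len(neighbors) if neighbors else 0.0,
        n_focal=len(focal),
        n_focal_induced=n_focal_induced,
        n_neighbors=len(neighbors),
        n_neighbors_induced=nb_induced,
        n_missing_neighbors=n_missing,
        per_focal=per_focal,
    )
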