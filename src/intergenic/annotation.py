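"""Gene-annotation geometry: collapsed gene spans and intergenic structure.

The coordinate substrate for the whole pipeline.  Genes are collapsed to one
span per ``gene_id`` (union of transcript extents) and stored 0-based,
half-open.  From the sorted per-chromosome gene order we derive:

* per-gene neighbor contexts -- the upstream gap ``x`` to the end of the
  nearest gene on the left, the downstream gap ``y`` to the start of the
  nearest gene on the right, and the intergenic length ``x + y``;
* adjacent gene pairs with their shared intergenic interval and an
  orientation class (divergent H-H, tandem T-H / H-T, convergent T-T).

Genes that overlap another gene have no well-defined intergenic region and
yield no neighbor context; the first and last gene of a chromosome lack one
flank and likewise yield none.  Overlapped genes still bound their
neighbors' gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import _io
from .errors import OrderingError, ValidationError

__all__ = [
    "EID_THRESHOLD_BP",
    "EXTENDED_THRESHOLD_BP",
    "SHORT_THRESHOLD_BP",
    "GeneRecord",
    "GeneUniverse",
    "load_gene_spans",
    "collapse_transcripts",
    "build_neighbor_contexts",
    "enumerate_gene_pairs",
    "classify_pair_orientation",
    "gene_length",
    "length_class",
]

#: Intergenic-length class thresholds (strict comparisons).
EID_THRESHOLD_BP = 500_000
EXTENDED_THRESHOLD_BP = 100_000
SHORT_THRESHOLD_BP = 10_000

_VALID_STRANDS = frozenset({"+", "-"})

#: (left strand, right strand) -> orientation of an adjacent gene pair.
#: Read left to right along the chromosome: a minus-strand left gene and a
#: plus-strand right gene point away from each other's bodies and transcribe
#: divergently (head-to-head).
_ORIENTATION = {
    ("-", "+"): "HH",
    ("+", "+"): "TH",
    ("-", "-"): "HT",
    ("+", "-"): "TT",
}

_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]


@dataclass(frozen=True)
class GeneRecord:
    """One collapsed protein-coding gene span (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: invalid strand {self.strand!r}"
            )


class GeneUniverse:
    """Sorted collection of collapsed gene spans, one per ``gene_id``.

    Parameters
    ----------
    genes
        DataFrame with columns ``gene_id, chrom, start, end, strand``
        (``biotype`` optional).  Sorted on construction by
        ``(chrom, start, end, gene_id)``.
    provenance
        Free-text note on where the annotation came from.
    """

    def __init__(self, genes: pd.DataFrame, provenance: str = ""):
        df = genes.copy()
        if "biotype" not in df.columns:
            df["biotype"] = "protein_coding"
        missing = [c for c in _GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"gene table missing columns: {missing}")
        df = df[_GENE_COLUMNS]
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValidationError(f"duplicate gene_id(s): {dups[:5]}")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
            raise ValidationError(f"start >= end for gene(s): {bad[:5]}")
        if not df["strand"].isin(list(_VALID_STRANDS)).all():
            bad = df.loc[~df["strand"].isin(list(_VALID_STRANDS)), "gene_id"]
            raise ValidationError(f"invalid strand for gene(s): {list(bad)[:5]}")
        df = df.sort_values(
            ["chrom", "start", "end", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self._df = df
        self.provenance = provenance

    @property
    def df(self) -> pd.DataFrame:
        """The sorted gene table (do not mutate)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterable[GeneRecord]:
        for row in self._df.itertuples(index=False):
            yield GeneRecord(
                row.gene_id, row.chrom, int(row.start), int(row.end),
                row.strand, row.biotype,
            )

    @classmethod
    def from_records(cls, records: Iterable[GeneRecord], provenance: str = ""):
        rows = [
            (g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype)
            for g in records
        ]
        return cls(pd.DataFrame(rows, columns=_GENE_COLUMNS), provenance)

    def by_chrom(self):
        """Yield ``(chrom, sub_df)`` in sorted chromosome order."""
        for chrom, sub in self._df.groupby("chrom", sort=True):
            yield chrom, sub

    def tss(self) -> pd.Series:
        """Strand-aware transcription start positions (0-based base), by gene_id.

        Plus-strand genes start at ``start``; minus-strand genes start at
        ``end - 1`` (the last base of the half-open span).
        """
        df = self._df
        pos = np.where(df["strand"].to_numpy() == "+",
                       df["start"].to_numpy(),
                       df["end"].to_numpy() - 1)
        return pd.Series(pos, index=df["gene_id"].to_numpy(), name="tss")


def collapse_transcripts(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-transcript table to one span per gene_id.

    The span is the union of transcript extents: ``(min start, max end)``.
    Genes whose transcripts disagree on strand or chromosome are dropped
    with a warning (their orientation would be undefined).
    """
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(transcripts.columns)
    if missing:
        raise ValidationError(f"transcript table missing columns: {sorted(missing)}")
    grp = transcripts.groupby("gene_id", sort=False)
    n_chrom = grp["chrom"].nunique()
    n_strand = grp["strand"].nunique()
    bad = set(n_chrom[n_chrom > 1].index) | set(n_strand[n_strand > 1].index)
    if bad:
        warnings.warn(
            f"dropped {len(bad)} gene(s) with transcripts on conflicting "
            f"strands or chromosomes: {sorted(bad)[:5]}",
            stacklevel=2,
        )
        transcripts = transcripts[~transcripts["gene_id"].isin(bad)]
        grp = transcripts.groupby("gene_id", sort=False)
    agg = {"chrom": "first", "start": "min", "end": "max", "strand": "first"}
    if "biotype" in transcripts.columns:
        agg["biotype"] = "first"
    out = grp.agg(agg).reset_index()
    return out


def load_gene_spans(
    annotation_source,
    biotype_filter: str | None = "protein_coding",
    fmt: str = "gtf",
) -> GeneUniverse:
    """Parse an annotation into a :class:`GeneUniverse` of collapsed spans.

    Parameters
    ----------
    annotation_source
        Path to the annotation file, or an already-parsed per-transcript
        DataFrame with columns ``gene_id, chrom, start, end, strand``.
    biotype_filter
        Keep only genes of this biotype (``None`` keeps everything; tables
        without a biotype column are kept in full).
    fmt
        ``"gtf"`` (1-based closed, converted on read), ``"refflat"`` or
        ``"bed"`` (both already 0-based half-open).
    """
    if isinstance(annotation_source, pd.DataFrame):
        tx = annotation_source
    elif fmt == "gtf":
        tx = _io.read_gtf_transcripts(annotation_source)
    elif fmt == "refflat":
        tx = _io.read_refflat(annotation_source)
    elif fmt == "bed":
        tx = _io.read_bed_genes(annotation_source)
    else:
        raise ValidationError(f"unknown annotation format {fmt!r}")
    genes = collapse_transcripts(tx)
    if biotype_filter is not None and "biotype" in genes.columns:
        genes = genes[genes["biotype"] == biotype_filter]
    return GeneUniverse(genes.reset_index(drop=True),
                        provenance=f"{fmt}:{annotation_source}"
                        if not isinstance(annotation_source, pd.DataFrame)
                        else "dataframe")


def gene_length(gene) -> int:
    """Distance between transcription start and end sites: ``end - start``.

    Operates on the collapsed span (union of isoform extents), not on the
    longest transcript.  Accepts a :class:`GeneRecord` or any object with
    ``start``/``end`` attributes or keys.
    """
    try:
        return int(gene.end) - int(gene.start)
    except AttributeError:
        return int(gene["end"]) - int(gene["start"])


def length_class(intergenic_length_bp) -> str | np.ndarray:
    """Map intergenic lengths to {EID, extended, intermediate, short}.

    Strict thresholds: EID > 500 kb, extended > 100 kb, short < 10 kb.
    Vectorized over arrays.
    """
    arr = np.asarray(intergenic_length_bp)
    out = np.where(
        arr > EID_THRESHOLD_BP, "EID",
        np.where(arr > EXTENDED_THRESHOLD_BP, "extended",
                 np.where(arr < SHORT_THRESHOLD_BP, "short", "intermediate")),
    )
    if arr.ndim == 0:
        return str(out)
    return out


def _check_sorted(df: pd.DataFrame):
    for _, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        if np.any(np.diff(s) < 0):
            raise OrderingError("gene universe is not sorted by start")


def _overlap_flags(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """True where a gene intersects any other gene (arrays sorted by start)."""
    n = len(starts)
    flags = np.zeros(n, dtype=bool)
    if n < 2:
        return flags
    prefix_max_end = np.maximum.accumulate(ends)
    # overlaps an earlier gene: some earlier end extends past this start
    flags[1:] |= prefix_max_end[:-1] > starts[1:]
    # overlaps a later gene: some later start falls before this end
    suffix_min_start = np.minimum.accumulate(starts[::-1])[::-1]
    flags[:-1] |= suffix_min_start[1:] < ends[:-1]
    return flags


def build_neighbor_contexts(universe: GeneUniverse) -> pd.DataFrame:
    """Compute the upstream/downstream gaps and intergenic length per gene.

    For a focal gene B the upstream gap is ``B.start`` minus the largest
    gene end among genes entirely to its left, and the downstream gap is
    the smallest gene start to its right minus ``B.end``; the intergenic
    length is their sum.  Genes that overlap another gene, and the first
    and last gene of each chromosome, yield no context.

    Returns a DataFrame with columns ``gene_id, chrom, upstream_gap_bp,
    downstream_gap_bp, intergenic_length_bp, left_neighbor_id,
    right_neighbor_id, length_class``.
    """
    df = universe.df
    _check_sorted(df)
    pieces = []
    for chrom, sub in universe.by_chrom():
        n = len(sub)
        if n < 3:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        overlapped = _overlap_flags(starts, ends)

        prefix_max_end = np.maximum.accumulate(ends)
        prefix_argmax = np.zeros(n, dtype=np.int64)
        for i in range(1, n):
            prefix_argmax[i] = i if ends[i] > ends[prefix_argmax[i - 1]] \
                else prefix_argmax[i - 1]
        suffix_min_start = np.minimum.accumulate(starts[::-1])[::-1]
        suffix_argmin = np.zeros(n, dtype=np.int64)
        suffix_argmin[-1] = n - 1
        for i in range(n - 2, -1, -1):
            suffix_argmin[i] = i if starts[i] < starts[suffix_argmin[i + 1]] \
                else suffix_argmin[i + 1]

        keep = ~overlapped
        keep[0] = keep[-1] = False
        idx = np.nonzero(keep)[0]
        if idx.size == 0:
            continue
        x = starts[idx] - prefix_max_end[idx - 1]
        y = suffix_min_start[idx + 1] - ends[idx]
        # a non-overlapped interior gene always has non-negative gaps
        assert (x >= 0).all() and (y >= 0).all()
        pieces.append(pd.DataFrame({
            "gene_id": ids[idx],
            "chrom": chrom,
            "upstream_gap_bp": x,
            "downstream_gap_bp": y,
            "intergenic_length_bp": x + y,
            "left_neighbor_id": ids[prefix_argmax[idx - 1]],
            "right_neighbor_id": ids[suffix_argmin[idx + 1]],
            "length_class": length_class(x + y),
        }))
    if not pieces:
        return pd.DataFrame(columns=[
            "gene_id", "chrom", "upstream_gap_bp", "downstream_gap_bp",
            "intergenic_length_bp", "left_neighbor_id", "right_neighbor_id",
            "length_class",
        ])
    return pd.concat(pieces, ignore_index=True)


def classify_pair_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation of an adjacent pair from its two strands.

    ``(-, +) -> HH`` divergent, ``(+, +) -> TH`` tandem on the upper strand,
    ``(-, -) -> HT`` tandem on the lower strand, ``(+, -) -> TT`` convergent.
    """
    try:
        return _ORIENTATION[(left_strand, right_strand)]
    except KeyError:
        raise ValidationError(
            f"invalid strand pair ({left_strand!r}, {right_strand!r})"
        ) from None


def enumerate_gene_pairs(universe: GeneUniverse) -> pd.DataFrame:
    """Enumerate adjacent, non-overlapping gene pairs per chromosome.

    The shared intergenic interval of a pair is ``[left.end, right.start)``;
    abutting genes (gap 0) are retained, strictly overlapping adjacent
    genes are skipped.

    Returns a DataFrame with columns ``left_gene_id, right_gene_id, chrom,
    left_strand, right_strand, orientation, shared_start, shared_end,
    shared_length_bp``.
    """
    df = universe.df
    _check_sorted(df)
    pieces = []
    for chrom, sub in universe.by_chrom():
        if len(sub) < 2:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        strands = sub["strand"].to_numpy()
        ok = ends[:-1] <= starts[1:]
        li = np.nonzero(ok)[0]
        ri = li + 1
        orient = np.array([
            _ORIENTATION[(a, b)] for a, b in zip(strands[li], strands[ri])
        ])
        pieces.append(pd.DataFrame({
            "left_gene_id": ids[li],
            "right_gene_id": ids[ri],
            "chrom": chrom,
            "left_strand": strands[li],
            "right_strand": strands[ri],
            "orientation": orient,
            "shared_start": ends[li],
            "shared_end": starts[ri],
            "shared_length_bp": starts[ri] - ends[li],
        }))
    if not pieces:
        return pd.DataFrame(columns=[
            "left_gene_id", "right_gene_id", "chrom", "left_strand",
            "right_strand", "orientation", "shared_start", "shared_end",
            "shared_length_bp",
        ])
    return pd.concat(pieces, ignore_index=True)
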