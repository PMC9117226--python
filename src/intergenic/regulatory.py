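"""Peak-based regulatory density of intergenic regions.

Peaks (ATAC accessible sites, H3K27ac-enriched regions) are reduced to
their interval midpoints.  A peak belongs to a gene's intergenic region
when its midpoint lies in the gene's upstream or downstream gap; because
the gap between two genes is part of both genes' intergenic regions, one
gap peak credits both flanking genes (this intentionally doubles raw
tallies relative to a per-gap count).

Derived quantities:

* per-gene, per-tissue intergenic peak counts;
* the active-enhancer subset -- H3K27ac peaks whose midpoints lie more
  than 3 kb from the nearest transcription start site;
* nearest-enhancer spacings within each flank gap;
* cross-tissue sharing of accessible sites: single-linkage clustering of
  pooled midpoints at 1 kb, labelled common (every panel tissue present),
  tissue-specific (exactly one), or partial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneUniverse
from .errors import ValidationError

__all__ = [
    "SiteClusters",
    "peak_midpoints",
    "count_intergenic_peaks",
    "filter_active_enhancers",
    "enhancer_spacing",
    "median_spacing_per_gene",
    "classify_site_sharing",
]


def peak_midpoints(peaks: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``midpoint`` column, floor((start + end) / 2).

    Any summit information (e.g. the narrowPeak summit offset) is ignored;
    the midpoint is the peak coordinate throughout.
    """
    out = peaks.copy()
    out["midpoint"] = (out["start"].to_numpy() + out["end"].to_numpy()) // 2
    return out


def _flank_intervals(contexts: pd.DataFrame,
                     universe: GeneUniverse) -> pd.DataFrame:
    """Upstream/downstream gap intervals per context gene.

    Columns: ``gene_id, chrom, lo, hi, flank``.
    """
    coords = universe.df.set_index("gene_id")[["start", "end"]]
    ctx = contexts.join(coords, on="gene_id")
    up = pd.DataFrame({
        "gene_id": ctx["gene_id"],
        "chrom": ctx["chrom"],
        "lo": ctx["start"] - ctx["upstream_gap_bp"],
        "hi": ctx["start"],
        "flank": "up",
    })
    down = pd.DataFrame({
        "gene_id": ctx["gene_id"],
        "chrom": ctx["chrom"],
        "lo": ctx["end"],
        "hi": ctx["end"] + ctx["downstream_gap_bp"],
        "flank": "down",
    })
    return pd.concat([up, down], ignore_index=True)


def count_intergenic_peaks(peaks: pd.DataFrame, contexts: pd.DataFrame,
                           universe: GeneUniverse) -> pd.DataFrame:
    """Per-gene intergenic peak counts, one column per tissue.

    A peak counts for a gene when its midpoint falls inside the gene's
    upstream or downstream gap.  Peaks on chromosomes absent from the
    annotation are skipped with a warning tally.  Rows cover every gene in
    ``contexts``.
    """
    peaks = peaks if "midpoint" in peaks.columns else peak_midpoints(peaks)
    known = set(universe.df["chrom"].unique())
    skipped = (~peaks["chrom"].isin(known)).sum()
    if skipped:
        warnings.warn(
            f"skipped {skipped} peak(s) on chromosomes absent from the "
            "annotation", stacklevel=2)
        peaks = peaks[peaks["chrom"].isin(known)]
    tissues = (list(pd.unique(peaks["tissue"]))
               if "tissue" in peaks.columns else ["all"])
    flanks = _flank_intervals(contexts, universe)
    counts = pd.DataFrame(0, index=pd.Index(contexts["gene_id"],
                                            name="gene_id"),
                          columns=tissues)
    for tissue in tissues:
        sub = peaks if tissue == "all" and "tissue" not in peaks.columns \
            else peaks[peaks["tissue"] == tissue]
        for chrom, fsub in flanks.groupby("chrom", sort=False):
            mids = np.sort(sub.loc[sub["chrom"] == chrom,
                                   "midpoint"].to_numpy())
            lo = np.searchsorted(mids, fsub["lo"].to_numpy(), side="left")
            hi = np.searchsorted(mids, fsub["hi"].to_numpy(), side="left")
            per_flank = pd.Series(hi - lo, index=fsub["gene_id"].to_numpy())
            per_gene = per_flank.groupby(level=0).sum()
            counts.loc[per_gene.index, tissue] += per_gene
    return counts


def filter_active_enhancers(peaks: pd.DataFrame, universe: GeneUniverse,
                            min_tss_distance: int = 3000) -> pd.DataFrame:
    """Keep peaks whose midpoints lie strictly more than ``min_tss_distance``
    bp from the nearest transcription start site.

    TSSs are the strand-aware 5' ends of the collapsed gene spans (one per
    gene).  Peaks on chromosomes with no annotated gene have no nearby TSS
    and are kept.
    """
    peaks = peaks if "midpoint" in peaks.columns else peak_midpoints(peaks)
    tss = universe.tss()
    gdf = universe.df
    tss_by_chrom = {
        chrom: np.sort(tss[sub["gene_id"]].to_numpy())
        for chrom, sub in universe.by_chrom()
    }
    keep = np.ones(len(peaks), dtype=bool)
    chroms = peaks["chrom"].to_numpy()
    mids = peaks["midpoint"].to_numpy()
    for chrom in pd.unique(chroms):
        sites = tss_by_chrom.get(chrom)
        if sites is None or len(sites) == 0:
            continue
        mask = chroms == chrom
        p = mids[mask]
        right = np.searchsorted(sites, p)
        d_right = np.where(right < len(sites),
                           np.abs(sites[np.clip(right, 0, len(sites) - 1)] - p),
                           np.iinfo(np.int64).max)
        d_left = np.where(right > 0,
                          np.abs(p - sites[np.clip(right - 1, 0, None)]),
                          np.iinfo(np.int64).max)
        keep[mask] = np.minimum(d_left, d_right) > min_tss_distance
    return peaks[keep].reset_index(drop=True)


def enhancer_spacing(active_enhancers: pd.DataFrame, contexts: pd.DataFrame,
                     universe: GeneUniverse) -> pd.DataFrame:
    """Consecutive-enhancer distances within each flank gap of each gene.

    Enhancer midpoints inside a flank gap are sorted and differenced;
    flanks with fewer than two enhancers contribute nothing.  Returns a
    long DataFrame ``gene_id, flank, spacing_bp``; pool it directly or
    reduce with :func:`median_spacing_per_gene` for group statistics.
    """
    peaks = (active_enhancers if "midpoint" in active_enhancers.columns
             else peak_midpoints(active_enhancers))
    flanks = _flank_intervals(contexts, universe)
    frames = []
    for chrom, fsub in flanks.groupby("chrom", sort=False):
        mids = np.sort(peaks.loc[peaks["chrom"] == chrom,
                                 "midpoint"].to_numpy())
        if len(mids) < 2:
            continue
        diffs = np.diff(mids)
        lo = np.searchsorted(mids, fsub["lo"].to_numpy(), side="left")
        hi = np.searchsorted(mids, fsub["hi"].to_numpy(), side="left")
        m = np.clip(hi - lo - 1, 0, None)          # spacings per flank
        total = int(m.sum())
        if total == 0:
            continue
        # index into `diffs` for every spacing of every flank
        starts = np.repeat(lo, m)
        offsets = np.arange(total) - np.repeat(np.cumsum(m) - m, m)
        frames.append(pd.DataFrame({
            "gene_id": np.repeat(fsub["gene_id"].to_numpy(), m),
            "flank": np.repeat(fsub["flank"].to_numpy(), m),
            "spacing_bp": diffs[starts + offsets],
        }))
    if not frames:
        return pd.DataFrame(columns=["gene_id", "flank", "spacing_bp"])
    out = pd.concat(frames, ignore_index=True)
    assert (out["spacing_bp"] >= 0).all()
    return out


def median_spacing_per_gene(spacings: pd.DataFrame) -> pd.Series:
    """Per-gene median of nearest-enhancer spacings."""
    return spacings.groupby("gene_id")["spacing_bp"].median()


@dataclass
class SiteClusters:
    """Cross-tissue clusters of accessible-site midpoints."""

    clusters: pd.DataFrame   # chrom, rep_midpoint, n_peaks, tissues, sharing_class, span_bp
    peaks: pd.DataFrame      # input peaks + cluster_id, sharing_class
    tissue_panel: tuple


def classify_site_sharing(peaks: pd.DataFrame, tissue_panel: Sequence[str],
                          link_distance: int = 1000) -> SiteClusters:
    """Cluster accessible sites across tissues and label their sharing.

    Midpoints pooled over all tissues are clustered per chromosome by
    single linkage at ``link_distance`` (chain proximity: consecutive
    sorted midpoints within the threshold join).  A cluster is *common*
    when every panel tissue contributes at least one peak, *specific* when
    exactly one tissue is present, else *partial*.  Pathological chains
    spanning more than 5 kb are possible under single linkage and are
    reported with a warning.
    """
    panel = tuple(tissue_panel)
    if not panel:
        raise ValidationError("tissue panel must be non-empty")
    peaks = peaks if "midpoint" in peaks.columns else peak_midpoints(peaks)
    peaks = peaks.sort_values(["chrom", "midpoint"],
                              kind="mergesort").reset_index(drop=True)
    mids = peaks["midpoint"].to_numpy()
    chrom_change = np.zeros(len(peaks), dtype=bool)
    if len(peaks):
        chroms = peaks["chrom"].to_numpy()
        chrom_change[1:] = chroms[1:] != chroms[:-1]
        far = np.zeros(len(peaks), dtype=bool)
        far[1:] = np.diff(mids) > link_distance
        cluster_id = np.cumsum(chrom_change | far)
    else:
        cluster_id = np.array([], dtype=np.int64)
    peaks = peaks.assign(cluster_id=cluster_id)

    grp = peaks.groupby("cluster_id", sort=True)
    clusters = grp.agg(
        chrom=("chrom", "first"),
        rep_midpoint=("midpoint", "median"),
        n_peaks=("midpoint", "size"),
        n_tissues=("tissue", "nunique"),
        first_tissue=("tissue", "first"),
        lo=("midpoint", "min"),
        hi=("midpoint", "max"),
    )
    clusters["rep_midpoint"] = clusters["rep_midpoint"].astype(np.int64)
    clusters["span_bp"] = clusters["hi"] - clusters["lo"]
    pairs = peaks[["cluster_id", "tissue"]].drop_duplicates().sort_values(
        ["cluster_id", "tissue"], kind="mergesort")
    clusters["tissues"] = pairs.groupby("cluster_id")["tissue"].agg(
        ",".join)
    n_panel = pairs[pairs["tissue"].isin(panel)].groupby(
        "cluster_id")["tissue"].size().reindex(clusters.index, fill_value=0)
    clusters["sharing_class"] = np.where(
        clusters["n_tissues"] == 1,
        "specific:" + clusters["first_tissue"].astype(object),
        np.where(n_panel == len(panel), "common", "partial"))
    clusters = clusters.reset_index()[[
        "cluster_id", "chrom", "rep_midpoint", "n_peaks", "tissues",
        "sharing_class", "span_bp"]]
    labels = dict(zip(clusters["cluster_id"], clusters["sharing_class"]))
    n_long = int((clusters["span_bp"] > 5000).sum())
    if n_long:
        warnings.warn(
            f"{n_long} single-linkage cluster(s) span more than 5 kb",
            stacklevel=2)
    peaks = peaks.assign(
        sharing_class=peaks["cluster_id"].map(labels))
    return SiteClusters(clusters=clusters, peaks=peaks, tissue_panel=panel)
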