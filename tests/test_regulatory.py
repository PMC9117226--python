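"""Intergenic peak counting, TSS filtering, spacing, cross-tissue sharing."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_universe
from intergenic import (
    GeneUniverse,
    SyntheticConfig,
    build_neighbor_contexts,
    classify_site_sharing,
    count_intergenic_peaks,
    enhancer_spacing,
    filter_active_enhancers,
    generate_bundle,
    peak_midpoints,
)
from intergenic.synthetic import NEURAL_TISSUES


def _universe(rows):
    return GeneUniverse(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def _peaks(rows, tissue="t"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["tissue"] = tissue
    return df


THREE_GENES = [("A", "chr1", 1000, 2000, "+"),
               ("B", "chr1", 5000, 6000, "+"),
               ("C", "chr1", 9000, 10000, "+"),
               ("D", "chr1", 15000, 16000, "+")]


def test_midpoint_is_floor_of_interval_center():
    df = peak_midpoints(pd.DataFrame({"chrom": ["c"], "start": [10],
                                      "end": [15]}))
    assert df.loc[0, "midpoint"] == 12


def test_gap_peak_credits_both_flanking_genes():
    uni = _universe(THREE_GENES)
    ctx = build_neighbor_contexts(uni)
    peaks = _peaks([("chr1", 7000, 7200)])  # midpoint 7100 in gap B-C
    counts = count_intergenic_peaks(peaks, ctx, uni)
    assert counts.loc["B", "t"] == 1
    assert counts.loc["C", "t"] == 1


def test_gene_body_peak_counts_for_nobody():
    uni = _universe(THREE_GENES)
    ctx = build_neighbor_contexts(uni)
    peaks = _peaks([("chr1", 5400, 5600)])  # midpoint inside gene B
    counts = count_intergenic_peaks(peaks, ctx, uni)
    assert (counts == 0).all().all()


def test_unknown_chromosome_skipped_with_warning():
    uni = _universe(THREE_GENES)
    ctx = build_neighbor_contexts(uni)
    peaks = _peaks([("chrUn", 7000, 7200), ("chr1", 7000, 7200)])
    with pytest.warns(UserWarning, match="skipped 1"):
        counts = count_intergenic_peaks(peaks, ctx, uni)
    assert counts.loc["B", "t"] == 1


def test_peak_counts_match_bruteforce_scan():
    """2,000 random peaks over a 300-gene genome (seed 4) vs O(n*m) scan."""
    rng = np.random.default_rng(4)
    uni = random_universe(rng, n_genes=300, n_chrom=3)
    ctx = build_neighbor_contexts(uni)
    max_pos = int(uni.df["end"].max())
    peaks = pd.DataFrame({
        "chrom": rng.choice([f"chr{i}" for i in range(3)], size=2000),
        "start": rng.integers(0, max_pos, size=2000),
    })
    peaks["end"] = peaks["start"] + 400
    peaks["tissue"] = "t"
    counts = count_intergenic_peaks(peaks, ctx, uni)

    coords = uni.df.set_index("gene_id")
    mids = peak_midpoints(peaks)
    for row in ctx.itertuples(index=False):
        g = coords.loc[row.gene_id]
        lo_u, hi_u = g.start - row.upstream_gap_bp, g.start
        lo_d, hi_d = g.end, g.end + row.downstream_gap_bp
        expected = sum(
            1 for p in mids.itertuples(index=False)
            if p.chrom == row.chrom
            and (lo_u <= p.midpoint < hi_u or lo_d <= p.midpoint < hi_d))
        assert counts.loc[row.gene_id, "t"] == expected


def test_tss_distance_threshold_is_strict():
    uni = _universe([("A", "chr1", 100_000, 101_000, "+")])  # TSS 100,000
    peaks = _peaks([("chr1", 103_000, 103_002),    # midpoint 103,001
                    ("chr1", 102_999, 103_001)])   # midpoint 103,000
    kept = filter_active_enhancers(peaks, uni)
    assert list(kept["midpoint"]) == [103_001]


def test_equidistant_peak_kept():
    uni = _universe([("A", "chr1", 10_000, 12_000, "+"),
                     ("B", "chr1", 20_000, 22_000, "+")])
    # TSSs at 10,000 and 20,000; midpoint 15,000 is 5 kb from both
    peaks = _peaks([("chr1", 14_900, 15_100)])
    assert len(filter_active_enhancers(peaks, uni)) == 1


def test_tss_filter_matches_bruteforce_min_distance():
    rng = np.random.default_rng(8)
    uni = random_universe(rng, n_genes=120, n_chrom=2)
    max_pos = int(uni.df["end"].max())
    peaks = pd.DataFrame({
        "chrom": rng.choice(["chr0", "chr1"], size=600),
        "start": rng.integers(0, max_pos, size=600),
    })
    peaks["end"] = peaks["start"] + 200
    kept = filter_active_enhancers(peaks, uni, min_tss_distance=3000)
    tss = uni.tss()
    gdf = uni.df
    kept_ids = set(zip(kept["chrom"], kept["start"]))
    for p in peak_midpoints(peaks).itertuples(index=False):
        dists = [abs(p.midpoint - tss[g])
                 for g, c in zip(gdf["gene_id"], gdf["chrom"]) if c == p.chrom]
        expected = min(dists) > 3000
        assert ((p.chrom, p.start) in kept_ids) == expected


def test_enlarging_tss_exclusion_never_grows_kept_set():
    rng = np.random.default_rng(15)
    uni = random_universe(rng, n_genes=80, n_chrom=2)
    peaks = pd.DataFrame({
        "chrom": rng.choice(["chr0", "chr1"], size=300),
        "start": rng.integers(0, int(uni.df["end"].max()), size=300),
    })
    peaks["end"] = peaks["start"] + 100
    prev = None
    for radius in (0, 1000, 3000, 10_000):
        kept = set(filter_active_enhancers(
            peaks, uni, min_tss_distance=radius)["start"])
        if prev is not None:
            assert kept <= prev
        prev = kept


def test_spacing_from_sorted_midpoints():
    uni = _universe([("A", "chr1", 1000, 2000, "+"),
                     ("B", "chr1", 50_000, 51_000, "+"),
                     ("C", "chr1", 90_000, 91_000, "+")])
    ctx = build_neighbor_contexts(uni)
    peaks = _peaks([("chr1", 9_900, 10_100),     # midpoints 10,000
                    ("chr1", 23_900, 24_100),    # 24,000
                    ("chr1", 25_400, 25_600)])   # 25,500 -- all in gap A-B
    sp = enhancer_spacing(peaks, ctx, uni)
    b_up = sp[(sp["gene_id"] == "B") & (sp["flank"] == "up")]
    assert sorted(b_up["spacing_bp"]) == [1500, 14_000]


def test_single_enhancer_per_flank_contributes_nothing():
    uni = _universe(THREE_GENES)
    ctx = build_neighbor_contexts(uni)
    peaks = _peaks([("chr1", 3000, 3200), ("chr1", 7000, 7200)])
    sp = enhancer_spacing(peaks, ctx, uni)
    assert len(sp) == 0


def test_poisson_spacing_matches_exponential_expectation():
    """Planted Poisson enhancers: median spacing ~ ln2 / rate (+-15%)."""
    rng = np.random.default_rng(13)
    gap = 400_000
    rows = []
    pos = 1000
    for i in range(40):  # 40 genes separated by 400-kb gaps
        rows.append((f"g{i}", "chr1", pos, pos + 2000, "+"))
        pos += 2000 + gap
    uni = _universe(rows)
    ctx = build_neighbor_contexts(uni)
    rate = 1 / 10_000  # one enhancer per 10 kb
    n = rng.poisson(rate * gap * 40)
    starts = rng.integers(0, pos, size=n)
    peaks = pd.DataFrame({"chrom": "chr1", "start": starts,
                          "end": starts + 100})
    sp = enhancer_spacing(peaks, ctx, uni)
    med = sp["spacing_bp"].median()
    assert med == pytest.approx(np.log(2) / rate, rel=0.15)


def test_chained_midpoints_form_one_common_cluster():
    peaks = pd.DataFrame({
        "chrom": "chr1",
        "start": [0, 500, 1000, 1500],
        "end": [200, 700, 1200, 1700],   # midpoints 100, 600, 1100, 1600
        "tissue": ["t1", "t2", "t3", "t4"],
    })
    sc = classify_site_sharing(peaks, ["t1", "t2", "t3", "t4"])
    assert len(sc.clusters) == 1
    assert sc.clusters.iloc[0].sharing_class == "common"


def test_isolated_single_tissue_peak_is_specific():
    peaks = pd.DataFrame({
        "chrom": "chr1", "start": [0, 5000], "end": [200, 5200],
        "tissue": ["t1", "t1"],
    })
    sc = classify_site_sharing(peaks, ["t1", "t2"])
    assert list(sc.clusters["sharing_class"]) == ["specific:t1"] * 2


def test_planted_sharing_labels_recovered(small_bundle):
    """Common/specific site labels recovered on the planted neural panel."""
    panel = list(NEURAL_TISSUES)
    peaks = small_bundle.atac[small_bundle.atac["tissue"].isin(panel)]
    sc = classify_site_sharing(peaks, panel)
    truth = small_bundle.truth.atac_sites.set_index("site_id")
    tlab = truth.loc[sc.peaks["site_id"], "sharing"].to_numpy()
    ttis = truth.loc[sc.peaks["site_id"], "tissue"].to_numpy()
    expected = np.where(tlab == "common", "common",
                        "specific:" + ttis.astype(object))
    acc = (sc.peaks["sharing_class"].to_numpy() == expected).mean()
    assert acc >= 0.99


def test_no_peak_lost_or_duplicated_across_clusters(small_bundle):
    panel = list(NEURAL_TISSUES)
    peaks = small_bundle.atac[small_bundle.atac["tissue"].isin(panel)]
    sc = classify_site_sharing(peaks, panel)
    assert len(sc.peaks) == len(peaks)
    assert sc.clusters["n_peaks"].sum() == len(peaks)
    assert sc.peaks["cluster_id"].notna().all()
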