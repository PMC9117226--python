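"""Gene-span collapsing, neighbor contexts, pair enumeration, orientation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intergenic import (
    GeneRecord,
    GeneUniverse,
    build_neighbor_contexts,
    classify_pair_orientation,
    enumerate_gene_pairs,
    gene_length,
    length_class,
    load_gene_spans,
)
from intergenic.errors import OrderingError, ValidationError


def _universe(rows):
    return GeneUniverse(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


# ------------------------------------------------------------ span collapse

def test_collapse_unions_isoform_extents():
    tx = pd.DataFrame({
        "gene_id": ["G", "G"], "chrom": ["chr1", "chr1"],
        "start": [100, 300], "end": [500, 900], "strand": ["+", "+"],
    })
    uni = load_gene_spans(tx)
    assert len(uni) == 1
    g = next(iter(uni))
    assert (g.start, g.end) == (100, 900)
    assert gene_length(g) == 800


def test_conflicting_strand_gene_dropped_with_warning():
    tx = pd.DataFrame({
        "gene_id": ["G", "G", "H"], "chrom": ["chr1"] * 3,
        "start": [100, 300, 1000], "end": [500, 900, 2000],
        "strand": ["+", "-", "+"],
    })
    with pytest.warns(UserWarning, match="conflicting"):
        uni = load_gene_spans(tx)
    assert [g.gene_id for g in uni] == ["H"]


def test_collapsed_spans_match_per_transcript_scan():
    """200 random multi-isoform genes: span == exhaustive min/max scan."""
    rng = np.random.default_rng(11)
    rows = []
    for i in range(200):
        n_tx = int(rng.integers(1, 5))
        base = int(rng.integers(0, 10_000_000))
        for _ in range(n_tx):
            s = base + int(rng.integers(0, 5000))
            e = s + int(rng.integers(100, 8000))
            rows.append((f"g{i}", f"chr{i % 4}", s, e, "+"))
    tx = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    uni = load_gene_spans(tx)
    # independent oracle: plain python scan over every transcript
    oracle = {}
    for gid, chrom, s, e, _ in rows:
        lo, hi = oracle.get(gid, (s, e))
        oracle[gid] = (min(lo, s), max(hi, e))
    assert len(uni) == 200
    for g in uni:
        assert (g.start, g.end) == oracle[g.gene_id]
        assert gene_length(g) == oracle[g.gene_id][1] - oracle[g.gene_id][0]


def test_gene_record_validation():
    with pytest.raises(ValidationError):
        GeneRecord("g", "chr1", 100, 100, "+")
    with pytest.raises(ValidationError):
        GeneRecord("g", "chr1", 0, 10, "x")


# -------------------------------------------------------- neighbor contexts

def test_context_sums_flanking_gaps():
    uni = _universe([("A", "chr1", 1000, 2000, "+"),
                     ("B", "chr1", 5000, 6000, "+"),
                     ("C", "chr1", 9000, 10000, "+")])
    ctx = build_neighbor_contexts(uni).set_index("gene_id")
    assert list(ctx.index) == ["B"]
    row = ctx.loc["B"]
    assert (row.upstream_gap_bp, row.downstream_gap_bp) == (3000, 3000)
    assert row.intergenic_length_bp == 6000
    assert (row.left_neighbor_id, row.right_neighbor_id) == ("A", "C")
    assert row.length_class == "short"


def test_overlapping_genes_excluded_from_context_set():
    # B starts before A ends: both lose their contexts
    uni = _universe([("A", "chr1", 1000, 3000, "+"),
                     ("B", "chr1", 2500, 4000, "+"),
                     ("C", "chr1", 9000, 10000, "+"),
                     ("D", "chr1", 20000, 21000, "+"),
                     ("E", "chr1", 30000, 31000, "+")])
    ctx = build_neighbor_contexts(uni)
    got = set(ctx["gene_id"])
    assert "A" not in got and "B" not in got
    assert {"C", "D"} <= got  # interior non-overlapped genes keep theirs


def test_unsorted_universe_rejected():
    uni = _universe([("A", "chr1", 1000, 2000, "+"),
                     ("B", "chr1", 5000, 6000, "+"),
                     ("C", "chr1", 9000, 10000, "+")])
    shuffled = uni.df.iloc[[2, 0, 1]].reset_index(drop=True)
    uni._df = shuffled  # bypass constructor sorting to simulate misuse
    with pytest.raises(OrderingError):
        build_neighbor_contexts(uni)


def _oracle_contexts(df):
    """Quadratic all-pairs nearest-gene search, one chromosome at a time."""
    out = {}
    for chrom, sub in df.groupby("chrom"):
        recs = list(sub.itertuples(index=False))
        for g in recs:
            others = [o for o in recs if o.gene_id != g.gene_id]
            if any(o.start < g.end and g.start < o.end for o in others):
                continue  # overlapped
            lefts = [o for o in others if o.end <= g.start]
            rights = [o for o in others if o.start >= g.end]
            if not lefts or not rights:
                continue  # terminal
            left = max(lefts, key=lambda o: o.end)
            right = min(rights, key=lambda o: o.start)
            out[g.gene_id] = (g.start - left.end, right.start - g.end,
                              left.gene_id, right.gene_id)
    return out


def test_contexts_match_quadratic_oracle():
    """1,000 random non-overlapping genes over 5 chromosomes, seed 3."""
    rng = np.random.default_rng(3)
    from conftest import random_universe
    uni = random_universe(rng, n_genes=1000, n_chrom=5)
    ctx = build_neighbor_contexts(uni)
    oracle = _oracle_contexts(uni.df)
    assert set(ctx["gene_id"]) == set(oracle)
    for row in ctx.itertuples(index=False):
        x, y, left, right = oracle[row.gene_id]
        assert (row.upstream_gap_bp, row.downstream_gap_bp) == (x, y)
        assert row.intergenic_length_bp == x + y
        assert (row.left_neighbor_id, row.right_neighbor_id) == (left, right)


def test_context_gaps_nonnegative_and_sum(default_bundle):
    ctx = build_neighbor_contexts(default_bundle.universe)
    assert (ctx["upstream_gap_bp"] >= 0).all()
    assert (ctx["downstream_gap_bp"] >= 0).all()
    assert (ctx["intergenic_length_bp"]
            == ctx["upstream_gap_bp"] + ctx["downstream_gap_bp"]).all()


def test_length_class_thresholds_are_strict():
    assert length_class(500_000) == "extended"
    assert length_class(500_001) == "EID"
    assert length_class(100_000) == "intermediate"
    assert length_class(100_001) == "extended"
    assert length_class(10_000) == "intermediate"
    assert length_class(9_999) == "short"


# -------------------------------------------------------------- gene pairs

def test_pair_shared_interval():
    uni = _universe([("A", "chr1", 0, 100, "+"),
                     ("B", "chr1", 400, 500, "+")])
    pairs = enumerate_gene_pairs(uni)
    assert len(pairs) == 1
    row = pairs.iloc[0]
    assert (row.shared_start, row.shared_end, row.shared_length_bp) \
        == (100, 400, 300)


def test_abutting_genes_retained_with_zero_shared_length():
    uni = _universe([("A", "chr1", 0, 100, "+"),
                     ("B", "chr1", 100, 200, "-")])
    pairs = enumerate_gene_pairs(uni)
    assert len(pairs) == 1
    assert pairs.iloc[0].shared_length_bp == 0


def test_pair_count_formula_on_random_chromosome():
    """Pairs = adjacencies minus overlapping adjacencies (seed 9)."""
    rng = np.random.default_rng(9)
    pos = 0
    rows = []
    for i in range(500):
        gap = int(rng.integers(-200, 3000))  # some negative -> overlaps
        pos = max(0, pos + gap)
        length = int(rng.integers(300, 1500))
        rows.append((f"g{i:03d}", "chr1", pos, pos + length, "+"))
        pos += length
    uni = _universe(rows)
    pairs = enumerate_gene_pairs(uni)
    df = uni.df
    n_overlap_adj = int((df["end"].to_numpy()[:-1]
                         > df["start"].to_numpy()[1:]).sum())
    assert len(pairs) == (len(df) - 1) - n_overlap_adj
    # linear-scan oracle of the retained adjacencies
    expected = [
        (df["gene_id"].iloc[i], df["gene_id"].iloc[i + 1])
        for i in range(len(df) - 1)
        if df["end"].iloc[i] <= df["start"].iloc[i + 1]
    ]
    got = list(zip(pairs["left_gene_id"], pairs["right_gene_id"]))
    assert got == expected


def test_shared_intervals_disjoint_per_chromosome(default_bundle):
    pairs = enumerate_gene_pairs(default_bundle.universe)
    for _, sub in pairs.groupby("chrom"):
        starts = sub["shared_start"].to_numpy()
        ends = sub["shared_end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()


# -------------------------------------------------------------- orientation

@pytest.mark.parametrize("left,right,expected", [
    ("-", "+", "HH"),   # divergent
    ("+", "+", "TH"),   # tandem, upper strand
    ("-", "-", "HT"),   # tandem, lower strand
    ("+", "-", "TT"),   # convergent
])
def test_orientation_case_table(left, right, expected):
    assert classify_pair_orientation(left, right) == expected


def test_orientation_rejects_bad_strand():
    with pytest.raises(ValidationError):
        classify_pair_orientation("+", ".")


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.sampled_from("+-"), min_size=4, max_size=30))
def test_strand_reversal_swaps_orientation_classes(strands):
    """Flipping every strand maps HH<->TT and TH<->HT, pairwise."""
    rows = [(f"g{i}", "chr1", i * 1000, i * 1000 + 500, s)
            for i, s in enumerate(strands)]
    flipped = [(g, c, s, e, "+" if st_ == "-" else "-")
               for (g, c, s, e, st_) in rows]
    p1 = enumerate_gene_pairs(_universe(rows))["orientation"]
    p2 = enumerate_gene_pairs(_universe(flipped))["orientation"]
    swap = {"HH": "TT", "TT": "HH", "TH": "HT", "HT": "TH"}
    assert list(p2) == [swap[o] for o in p1]


def test_orientation_classes_partition_all_pairs(default_bundle):
    pairs = enumerate_gene_pairs(default_bundle.universe)
    assert pairs["orientation"].isin(["HH", "TH", "HT", "TT"]).all()
    counts = pairs["orientation"].value_counts()
    assert counts.sum() == len(pairs)
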