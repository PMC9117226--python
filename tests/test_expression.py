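"""Normalization, induction levels, top-k selection, breadth classes."""

import numpy as np
import pandas as pd
import pytest

from intergenic import (
    SyntheticConfig,
    classify_breadth,
    compute_induction,
    generate_bundle,
    median_normalize,
    normalize_and_log,
    round_half_away_from_zero,
    select_top_fraction,
)
from intergenic.errors import NormalizationError, ValidationError
from intergenic.synthetic import NEURAL_TISSUES, NONNEURAL_TISSUES


def _matrix(values, samples, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)


# ------------------------------------------------------------ normalization

def test_median_normalization_divides_by_sample_median():
    m = _matrix([[4.0], [2.0], [1.0]], ["a"])  # median 2.0
    norm, log10, _ = normalize_and_log(m)
    assert norm.loc["g0", "a"] == pytest.approx(2.0)
    assert log10.loc["g0", "a"] == pytest.approx(np.log10(2.1))


def test_pseudocount_floors_zero_fpkm_at_minus_one():
    m = _matrix([[0.0], [1.0], [2.0]], ["a"])
    _, log10, _ = normalize_and_log(m)
    assert log10.loc["g0", "a"] == pytest.approx(np.log10(0.1)) == -1.0


def test_zero_median_names_offending_sample():
    m = _matrix([[0.0, 1.0], [0.0, 2.0], [1.0, 3.0]], ["bad", "good"])
    with pytest.raises(NormalizationError, match="bad"):
        median_normalize(m)


def test_normalized_medians_are_exactly_one():
    rng = np.random.default_rng(5)
    m = _matrix(rng.lognormal(1, 1, size=(1000, 6)),
                [f"s{i}" for i in range(6)])
    norm = median_normalize(m)
    assert np.allclose(norm.median(axis=0), 1.0)


def test_median_normalization_is_idempotent():
    rng = np.random.default_rng(5)
    m = _matrix(rng.lognormal(1, 1, size=(500, 4)),
                [f"s{i}" for i in range(4)])
    once = median_normalize(m)
    twice = median_normalize(once)
    pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------- induction

def test_induction_is_log2_ratio_of_pseudocounted_values():
    # normalized 3.9 in tissue vs 0.9 in reference -> log2(4.0 / 1.0) = 2
    m = _matrix([[3.9, 0.9]], ["tissue", "ES"])
    ind = compute_induction(m, "ES", normalize=False)
    assert ind.log2fc.loc["g0", "tissue"] == pytest.approx(2.0)


def test_reference_column_induction_is_zero():
    rng = np.random.default_rng(0)
    m = _matrix(rng.lognormal(0, 1, size=(50, 3)), ["a", "b", "ES"])
    ind = compute_induction(m, "ES")
    assert np.allclose(ind.log2fc["ES"], 0.0)


def test_missing_reference_rejected():
    m = _matrix([[1.0]], ["a"])
    with pytest.raises(ValidationError):
        compute_induction(m, "ES")


def test_exponentiating_log2fc_recovers_ratio():
    rng = np.random.default_rng(5)
    m = _matrix(rng.lognormal(0, 1, size=(300, 4)), ["a", "b", "c", "ES"])
    ind = compute_induction(m, "ES")
    shifted = ind.normalized + ind.pseudocount
    ratio = shifted.div(shifted["ES"], axis=0)
    assert np.allclose(2.0 ** ind.log2fc, ratio)
    assert np.isfinite(ind.log2fc.to_numpy()).all()


# ---------------------------------------------------------- top-k selection

@pytest.mark.parametrize("fraction,universe,expected", [
    (0.05, 18_383, 919),
    (0.05, 19_268, 963),
    (0.05, 9_897, 495),    # floor would give 494
    (0.10, 17_804, 1_780),
])
def test_top_fraction_reproduces_printed_set_sizes(fraction, universe,
                                                   expected):
    assert round_half_away_from_zero(fraction * universe) == expected
    rng = np.random.default_rng(1)
    col = pd.Series(rng.normal(size=universe),
                    index=[f"g{i:05d}" for i in range(universe)])
    assert len(select_top_fraction(col, fraction)) == expected


def test_top_fraction_tie_break_is_lexicographic():
    col = pd.Series([5.0, 5.0, 5.0, 1.0], index=["gb", "ga", "gc", "gd"])
    top = select_top_fraction(col, 0.5, universe_size=4)
    assert list(top) == ["ga", "gb"]


def test_top_fraction_rejects_bad_fraction():
    col = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValidationError):
        select_top_fraction(col, 1.5)


# ------------------------------------------------------------ gene classes

def test_housekeeping_requires_all_tissues_above_twofold():
    fc = pd.DataFrame(
        [[1.5, 2.0, 1.1, 1.4, 1.2, 3.0],     # all > 1 -> housekeeping
         [1.5, 2.0, 1.1, 1.4, 0.9, 3.0]],    # one tissue at 1.9-fold
        index=["hk", "not_hk"],
        columns=["n1", "n2", "n3", "nn1", "nn2", "nn3"])
    labels = classify_breadth(fc, ["n1", "n2", "n3"], ["nn1", "nn2", "nn3"])
    assert bool(labels.housekeeping["hk"])
    assert not bool(labels.housekeeping["not_hk"])


def test_generic_neural_tolerates_subthreshold_nonneural():
    # >2-fold in all neural tissues, 1.9-fold (log2 ~ 0.926) in one
    # non-neural tissue: the strict 2-fold rule keeps it generic neural
    fc = pd.DataFrame(
        [[2.0, 1.5, 3.0, 1.2, np.log2(1.9), 0.0, -1.0, 0.5]],
        index=["g"],
        columns=list(NEURAL_TISSUES) + list(NONNEURAL_TISSUES))
    labels = classify_breadth(fc, NEURAL_TISSUES, NONNEURAL_TISSUES)
    assert bool(labels.generic_neural["g"])
    assert not bool(labels.housekeeping["g"])


def test_housekeeping_and_generic_neural_mutually_exclusive(small_bundle):
    ind = compute_induction(small_bundle.expression, "ES")
    labels = classify_breadth(ind, NEURAL_TISSUES, NONNEURAL_TISSUES)
    assert not (labels.housekeeping & labels.generic_neural).any()


def test_planted_class_labels_recovered_exactly_without_noise():
    bundle = generate_bundle(SyntheticConfig(
        seed=21, n_chromosomes=2, genes_per_chromosome=600,
        noise_sigma=0.0))
    ind = compute_induction(bundle.expression, "ES")
    labels = classify_breadth(ind, NEURAL_TISSUES, NONNEURAL_TISSUES)
    truth = bundle.truth.genes.set_index("gene_id")
    assert (labels.housekeeping.reindex(truth.index)
            == (truth["class_label"] == "housekeeping")).all()
    assert (labels.generic_neural.reindex(truth.index)
            == (truth["class_label"] == "generic_neural")).all()


def test_planted_class_labels_recovered_under_default_noise():
    bundle = generate_bundle(SyntheticConfig(
        seed=21, n_chromosomes=2, genes_per_chromosome=1000))
    ind = compute_induction(bundle.expression, "ES")
    labels = classify_breadth(ind, NEURAL_TISSUES, NONNEURAL_TISSUES)
    truth = bundle.truth.genes.set_index("gene_id")
    hk = truth["class_label"] == "housekeeping"
    gn = truth["class_label"] == "generic_neural"
    assert labels.housekeeping.reindex(truth.index)[hk].mean() >= 0.95
    assert labels.generic_neural.reindex(truth.index)[gn].mean() >= 0.95


def test_breadth_excludes_housekeeping_genes(small_bundle):
    ind = compute_induction(small_bundle.expression, "ES")
    labels = classify_breadth(ind, NEURAL_TISSUES, NONNEURAL_TISSUES)
    assert (labels.breadth[labels.housekeeping] == 0).all()
    assert labels.breadth.between(0, len(NEURAL_TISSUES)).all()


def test_empty_tissue_set_rejected():
    fc = pd.DataFrame([[1.0]], index=["g"], columns=["t"])
    with pytest.raises(ValidationError):
        classify_breadth(fc, [], ["t"])
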