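"""Expression normalization, induction levels, and expression-based gene classes.

The expression substrate is a gene x sample matrix of FPKM values.  When
tissues are compared, each sample is first divided by its median FPKM over
all genes (median normalization), a pseudocount of 0.1 is added before any
logarithm, and the induction level of a gene in a tissue is the log2
fold-change of the pseudocounted, normalized value relative to a reference
sample (ES cells for tissue panels, an unstimulated control for stimulus
experiments).

Gene classes derived here:

* top-k% induced genes per tissue (round-half-away-from-zero set sizes,
  ties broken by gene_id so runs are reproducible);
* housekeeping genes -- induced more than 2-fold in every tissue of the
  panel;
* generic neural genes -- induced more than 2-fold in every neural tissue
  and in no non-neural tissue;
* expression breadth -- in how many tissues' top-k sets a gene appears,
  with housekeeping genes excluded from the overlap counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError

__all__ = [
    "InductionTable",
    "GeneClassLabels",
    "median_normalize",
    "normalize_and_log",
    "compute_induction",
    "round_half_away_from_zero",
    "select_top_fraction",
    "classify_breadth",
]

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class InductionTable:
    """Per-gene, per-sample induction levels and absolute expression.

    Attributes
    ----------
    log2fc
        gene x sample log2 fold-change versus ``reference_sample``
        (finite everywhere; the pseudocount guarantees it).
    log10expr
        gene x sample log10 of pseudocounted normalized expression.
    normalized
        median-normalized expression (no pseudocount applied).
    reference_sample
        the column all fold-changes are taken against.
    """

    log2fc: pd.DataFrame
    log10expr: pd.DataFrame
    normalized: pd.DataFrame
    reference_sample: str
    pseudocount: float = DEFAULT_PSEUDOCOUNT


@dataclass
class GeneClassLabels:
    """Expression-breadth gene classes over a tissue panel."""

    housekeeping: pd.Series          # bool per gene
    generic_neural: pd.Series        # bool per gene
    top_k: pd.DataFrame              # bool, gene x tissue
    breadth: pd.Series               # int per gene (housekeeping -> 0)
    neural_tissues: tuple = field(default_factory=tuple)
    nonneural_tissues: tuple = field(default_factory=tuple)


def median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample (column) by its median over all genes.

    The normalizer is the per-sample median over every gene in the table,
    zeros included.  A zero median raises :class:`NormalizationError`
    naming the sample.
    """
    if matrix.empty:
        raise ValidationError("expression matrix is empty")
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("FPKM values must be non-negative")
    medians = matrix.median(axis=0)
    zero = medians[medians == 0]
    if len(zero):
        raise NormalizationError(
            f"zero median FPKM in sample(s): {list(zero.index)}")
    return matrix / medians


def normalize_and_log(matrix: pd.DataFrame,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Median-normalize then compute the pseudocounted log layers.

    Returns ``(normalized, log10expr, log2expr)``; downstream induction is
    computed from ``normalized`` by :func:`compute_induction`.
    """
    norm = median_normalize(matrix)
    log10expr = np.log10(norm + pseudocount)
    log2expr = np.log2(norm + pseudocount)
    return norm, log10expr, log2expr


def compute_induction(matrix: pd.DataFrame, reference_sample: str,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      normalize: bool = True) -> InductionTable:
    """Build the full induction table for a gene x sample FPKM matrix.

    ``log2fc[g, t] = log2((norm[g, t] + pc) / (norm[g, ref] + pc))``.
    """
    if reference_sample not in matrix.columns:
        raise ValidationError(
            f"reference sample {reference_sample!r} not in matrix columns")
    norm = median_normalize(matrix) if normalize else matrix
    shifted = norm + pseudocount
    ref = shifted[reference_sample]
    log2fc = np.log2(shifted.div(ref, axis=0))
    log10expr = np.log10(shifted)
    return InductionTable(
        log2fc=log2fc,
        log10expr=log10expr,
        normalized=norm,
        reference_sample=reference_sample,
        pseudocount=pseudocount,
    )


def round_half_away_from_zero(x: float) -> int:
    """Round with ties going away from zero (1780.5 -> 1781, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def select_top_fraction(induction_column: pd.Series, fraction: float,
                        universe_size: int | None = None) -> pd.Index:
    """The top-``fraction`` most induced genes, at the exact mandated size.

    The set size is ``round_half_away_from_zero(fraction * universe_size)``
    (this reproduces 919 of 18,383 and 495 of 9,897 at 5%, and 1,780 of
    17,804 at 10%).  Genes are ranked by induction descending; ties at the
    boundary are broken by gene_id lexicographic order.
    """
    if not (0 < fraction < 1):
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    if universe_size is None:
        universe_size = len(induction_column)
    k = round_half_away_from_zero(fraction * universe_size)
    df = induction_column.rename("value").rename_axis("gene_id").reset_index()
    df = df.sort_values(["value", "gene_id"], ascending=[False, True],
                        kind="mergesort")
    return pd.Index(df["gene_id"].head(k))


def classify_breadth(induction: InductionTable | pd.DataFrame,
                     neural_tissues, nonneural_tissues,
                     fold_threshold: float = 2.0,
                     top_fraction: float = 0.10) -> GeneClassLabels:
    """Derive housekeeping / generic-neural flags and expression breadth.

    A gene is *housekeeping* if induced more than ``fold_threshold``-fold
    (strictly) in every tissue of the panel, and *generic neural* if so
    induced in every neural tissue but in no non-neural tissue; the two are
    mutually exclusive by construction.  Breadth counts in how many neural
    tissues' top-``top_fraction`` sets the gene appears; housekeeping genes
    are excluded from the overlap counts (breadth 0).
    """
    log2fc = induction.log2fc if isinstance(induction, InductionTable) \
        else induction
    neural_tissues = list(neural_tissues)
    nonneural_tissues = list(nonneural_tissues)
    if not neural_tissues or not nonneural_tissues:
        raise ValidationError("tissue sets must be non-empty")
    for t in neural_tissues + nonneural_tissues:
        if t not in log2fc.columns:
            raise ValidationError(f"tissue {t!r} not in induction table")
    thr = math.log2(fold_threshold)
    induced = log2fc > thr
    all_tissues = neural_tissues + nonneural_tissues
    housekeeping = induced[all_tissues].all(axis=1)
    generic_neural = (
        induced[neural_tissues].all(axis=1)
        & ~induced[nonneural_tissues].any(axis=1)
    )
    top_k = pd.DataFrame(False, index=log2fc.index, columns=all_tissues)
    for t in all_tissues:
        top_k.loc[select_top_fraction(log2fc[t], top_fraction), t] = True
    breadth = top_k[neural_tissues].sum(axis=1).astype(int)
    breadth[housekeeping] = 0
    return GeneClassLabels(
        housekeeping=housekeeping,
        generic_neural=generic_neural,
        top_k=top_k,
        breadth=breadth,
        neural_tissues=tuple(neural_tissues),
        nonneural_tissues=tuple(nonneural_tissues),
    )
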