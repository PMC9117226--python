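"""Binned trend curves and pairwise significance matrices.

The genome-wide trends relating intergenic length to expression are shown
as binned mean curves: genes sorted by one variable (descending), grouped
into bins of 200 genes (the remainder merged into the last bin, so 18,383
genes yield exactly 91 bins), per-bin means of both variables, and a
centered 3-bin moving average truncated at the edges.

Group differences (e.g. intergenic lengths of top-5% sets between tissues)
are summarized as a symmetric matrix of two-sided, pooled-variance
two-sample t-test P-values with no multiple-testing adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["BinnedCurve", "PairwisePMatrix", "binned_mean_curve",
           "pairwise_group_tests"]


@dataclass
class BinnedCurve:
    """A binned mean curve of one response against one ordering variable."""

    sort_key: str
    bin_size: int
    bin_x: np.ndarray        # per-bin mean of the ordering variable
    bin_y: np.ndarray        # per-bin mean of the response
    smoothed: np.ndarray     # moving average of bin_y, truncated at edges
    bin_counts: np.ndarray   # genes per bin (last bin absorbs the remainder)

    @property
    def n_bins(self) -> int:
        return len(self.bin_y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(self.n_bins),
            "mean_x": self.bin_x,
            "mean_y": self.bin_y,
            "smoothed_y": self.smoothed,
            "n_genes": self.bin_counts,
        })


@dataclass
class PairwisePMatrix:
    """Symmetric matrix of two-sided two-sample t-test P-values."""

    labels: tuple
    p: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.p


def moving_average(y: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; the window truncates at the two edges."""
    s = pd.Series(y)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def binned_mean_curve(values, sort_by, bin_size: int = 200,
                      smooth_window: int = 3,
                      sort_key: str = "sort_by") -> BinnedCurve:
    """Bin genes by a sort variable and average a response per bin.

    Genes are sorted by ``sort_by`` descending and partitioned into
    ``floor(N / bin_size)`` bins of ``bin_size`` genes; remainder genes are
    merged into the final bin.  Per-bin means of both the sort variable and
    the response are returned along with the edge-truncated centered moving
    average of the response means.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(sort_by, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("values and sort_by must be 1-D and aligned")
    n = len(y)
    if n < bin_size:
        raise ValidationError(
            f"need at least bin_size={bin_size} genes, got {n}")
    order = np.argsort(-x, kind="mergesort")
    x, y = x[order], y[order]
    n_bins = n // bin_size
    edges = np.arange(1, n_bins) * bin_size  # last bin takes the remainder
    x_bins = np.split(x, edges)
    y_bins = np.split(y, edges)
    bin_x = np.array([b.mean() for b in x_bins])
    bin_y = np.array([b.mean() for b in y_bins])
    counts = np.array([len(b) for b in y_bins])
    return BinnedCurve(
        sort_key=sort_key,
        bin_size=bin_size,
        bin_x=bin_x,
        bin_y=bin_y,
        smoothed=moving_average(bin_y, smooth_window),
        bin_counts=counts,
    )


def _t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance t-test P; degenerate zero-variance cases
    resolve by the mean difference (equal means -> 1, different -> 0)."""
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p):
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return p


def pairwise_group_tests(groups: Mapping[str, Sequence[float]]
                         ) -> PairwisePMatrix:
    """All-pairs two-sided, pooled-variance two-sample t-tests.

    P-values are not adjusted for multiple comparisons.  Every group needs
    at least two values; violations raise :class:`ValidationError` naming
    the group.
    """
    labels = tuple(groups.keys())
    arrays = {}
    for name in labels:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise ValidationError(
                f"group {name!r} has {arr.size} value(s); need >= 2")
        arrays[name] = arr
    p = pd.DataFrame(1.0, index=list(labels), columns=list(labels))
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            pv = _t_pvalue(arrays[a], arrays[b])
            p.loc[a, b] = pv
            p.loc[b, a] = pv
    return PairwisePMatrix(labels=labels, p=p)
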